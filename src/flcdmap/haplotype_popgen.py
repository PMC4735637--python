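"""Population-genetic statistics on haplotype alignments.

From a multi-FASTA alignment of a locus: uncorrected p-distances with
pairwise deletion, neighbour-joining clustering of the haplotypes into two
haplogroups (the two sides of the longest internal branch), per-SNP Hudson
FST between the groups, segregating-site and fixed-difference counts, mean
between-group divergence (Dxy), and a windowed incomplete-lineage-sorting
scan that flags regions where the two haplogroups are further from each
other than either is from the outgroup.

Gaps and ambiguity codes are treated as missing data throughout (a long
outgroup indel is missing sequence, not a stack of differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .errors import InputError, ParameterError


@dataclass
class HaplotypeAlignment:
    """Aligned haplotype sequences with sample and population labels.

    ``seqs`` is an (n_sequences, length) array of single characters;
    ``subregion`` (e.g. enhancer coordinates within the alignment) is
    0-based half-open.  The outgroup, when present, is excluded from all
    ingroup statistics.
    """

    ids: list[str]
    seqs: np.ndarray
    populations: dict[str, str] | None = None
    outgroup_id: str | None = None
    subregion: tuple[int, int] | None = None
    site_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.seqs = np.asarray(self.seqs, dtype="<U1")
        if self.seqs.ndim != 2 or self.seqs.shape[0] != len(self.ids):
            raise InputError("need one aligned row per sequence id")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("sequence ids must be unique")
        if self.outgroup_id is not None and self.outgroup_id not in self.ids:
            raise InputError(f"outgroup id {self.outgroup_id!r} not in alignment")

    @property
    def length(self) -> int:
        return int(self.seqs.shape[1])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def ingroup_ids(self) -> list[str]:
        return [i for i in self.ids if i != self.outgroup_id]

    def row(self, seq_id: str) -> np.ndarray:
        return self.seqs[self.ids.index(seq_id)]

    def matrix(self, ids) -> np.ndarray:
        return self.seqs[[self.ids.index(i) for i in ids]]

    def slice(self, start: int, end: int) -> "HaplotypeAlignment":
        """Columns [start, end) as a new alignment (0-based half-open)."""
        if not (0 <= start < end <= self.length):
            raise ParameterError("slice outside alignment")
        return HaplotypeAlignment(
            ids=list(self.ids),
            seqs=self.seqs[:, start:end].copy(),
            populations=self.populations,
            outgroup_id=self.outgroup_id,
        )

    def to_fasta(self, path):
        records = [
            SeqRecord(Seq("".join(row)), id=sid, description="")
            for sid, row in zip(self.ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, outgroup_id=None, populations=None,
                   subregion=None) -> "HaplotypeAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise InputError(f"{path}: no sequences")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise InputError("sequences are not aligned (unequal lengths)")
        seqs = np.array([list(str(r.seq).upper()) for r in records], dtype="<U1")
        return cls(
            ids=[r.id for r in records],
            seqs=seqs,
            populations=populations,
            outgroup_id=outgroup_id,
            subregion=subregion,
        )


@dataclass
class HaplogroupAssignment:
    """Two-group labelling of the ingroup haplotypes.

    Group "A" is the side of the defining bipartition containing the
    lexicographically smallest sequence id (a deterministic convention).
    """

    group_of: dict[str, str]
    branch_length: float

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == label]


# ----------------------------------------------------------- distances -----

def _diff_valid(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    valid = np.isin(a, ("A", "C", "G", "T")) & np.isin(b, ("A", "C", "G", "T"))
    return int((a[valid] != b[valid]).sum()), int(valid.sum())


def p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Uncorrected proportion of differing sites, pairwise deletion of
    gaps/ambiguities."""
    diff, valid = _diff_valid(a, b)
    if valid == 0:
        raise InputError("no comparable sites between a sequence pair")
    return diff / valid


def pairwise_distances(aln: HaplotypeAlignment, ids=None) -> DistanceMatrix:
    """Symmetric p-distance matrix over ``ids`` (default: all sequences)."""
    ids = list(ids) if ids is not None else list(aln.ids)
    if len(ids) < 2:
        raise InputError("need at least two sequences")
    m = aln.matrix(ids)
    valid = np.isin(m, ("A", "C", "G", "T"))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nv = int(both.sum())
            if nv == 0:
                raise InputError(f"no comparable sites between {ids[i]} and {ids[j]}")
            d[i, j] = d[j, i] = (m[i, both] != m[j, both]).sum() / nv
    return DistanceMatrix(d, ids)


# ------------------------------------------------------------------ NJ -----

def nj_tree(dm: DistanceMatrix):
    """Saitou-Nei neighbour joining; negative branch lengths clamped to 0.

    Returns an unrooted ``skbio.TreeNode`` (trifurcating root).
    """
    if dm.shape[0] < 3:
        raise InputError("neighbour joining needs at least 3 taxa")
    tree = _skbio_nj(dm, neg_as_zero=True)
    return tree


def assign_haplogroups(tree, ingroup_ids=None) -> HaplogroupAssignment:
    """Split the haplotypes on the longest internal branch of the NJ tree.

    The bipartition induced by the longest internal edge (an edge with at
    least two tips on each side) defines the two haplogroups.  Ties are
    broken deterministically towards the bipartition whose smallest member
    id is lexicographically smallest.  A star tree (no internal branch of
    positive length) has no haplogroup structure and raises.
    """
    all_tips = sorted(t.name for t in tree.tips())
    if ingroup_ids is not None:
        extra = set(all_tips) - set(ingroup_ids)
        if extra:
            raise InputError(
                f"tree contains non-ingroup tips {sorted(extra)}; "
                "build the tree from ingroup sequences only"
            )
    n = len(all_tips)
    best = None
    for node in tree.preorder(include_self=False):
        if node.is_tip():
            continue
        side = sorted(t.name for t in node.tips())
        if len(side) < 2 or n - len(side) < 2:
            continue
        length = node.length or 0.0
        key = (-length, min(side))
        if best is None or key < best[0]:
            best = (key, side, length)
    if best is None or best[2] <= 0.0:
        raise InputError("no haplogroup structure (star tree)")
    _, side, length = best
    other = [t for t in all_tips if t not in set(side)]
    if min(side) < min(other):
        a_side, b_side = side, other
    else:
        a_side, b_side = other, side
    group_of = {s: "A" for s in a_side}
    group_of.update({s: "B" for s in b_side})
    return HaplogroupAssignment(group_of=group_of, branch_length=float(length))


# ----------------------------------------------------------------- FST -----

def _site_freqs(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site allele counts over ACGT (4, L) and valid sample sizes (L,)."""
    counts = np.stack([(m == b).sum(axis=0) for b in "ACGT"])
    return counts, counts.sum(axis=0)


def per_snp_fst(aln: HaplotypeAlignment, assignment: HaplogroupAssignment) -> np.ndarray:
    """Hudson-type per-site FST between the two haplogroups.

    ``FST = 1 - Hw / Hb`` with Hw the mean of the two within-group unbiased
    heterozygosities ``(1 - sum p^2) * n/(n-1)`` and Hb the between-group
    heterozygosity ``1 - sum p_A p_B``.  Sites monomorphic across both
    groups (Hb = 0) or with fewer than two valid alleles in either group
    are missing (NaN).  Values can be slightly negative in finite samples.
    """
    ma = aln.matrix(assignment.members("A"))
    mb = aln.matrix(assignment.members("B"))
    ca, na = _site_freqs(ma)
    cb, nb = _site_freqs(mb)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = ca / na
        pb = cb / nb
        hw_a = (1.0 - (pa**2).sum(axis=0)) * na / (na - 1)
        hw_b = (1.0 - (pb**2).sum(axis=0)) * nb / (nb - 1)
        hw = (hw_a + hw_b) / 2.0
        hb = 1.0 - (pa * pb).sum(axis=0)
        fst = 1.0 - hw / hb
    fst[(na < 2) | (nb < 2)] = np.nan
    fst[hb == 0] = np.nan
    return fst


def site_counts(
    aln: HaplotypeAlignment,
    assignment: HaplogroupAssignment,
    subregion: tuple[int, int] | None = None,
):
    """Segregating sites and between-group fixed differences of the ingroup.

    A site is segregating when >= 2 distinct valid alleles occur among the
    ingroup; it is a fixed difference when each group is monomorphic (among
    its valid alleles) for a different allele.  ``subregion`` (0-based
    half-open, defaulting to the alignment's annotated subregion when
    ``subregion="annotated"``) restricts the counts.

    Returns ``(n_segregating, n_fixed, segregating_columns, fixed_columns)``.
    """
    lo, hi = 0, aln.length
    if subregion == "annotated":
        if aln.subregion is None:
            raise InputError("alignment has no annotated subregion")
        lo, hi = aln.subregion
    elif subregion is not None:
        lo, hi = subregion
    ma = aln.matrix(assignment.members("A"))[:, lo:hi]
    mb = aln.matrix(assignment.members("B"))[:, lo:hi]
    ca, na = _site_freqs(ma)
    cb, nb = _site_freqs(mb)
    tot = ca + cb
    n_alleles = (tot > 0).sum(axis=0)
    seg = n_alleles >= 2
    mono_a = ((ca > 0).sum(axis=0) == 1) & (na > 0)
    mono_b = ((cb > 0).sum(axis=0) == 1) & (nb > 0)
    allele_a = np.argmax(ca, axis=0)
    allele_b = np.argmax(cb, axis=0)
    fixed = mono_a & mono_b & (allele_a != allele_b)
    seg_cols = np.flatnonzero(seg) + lo
    fixed_cols = np.flatnonzero(fixed) + lo
    return int(seg.sum()), int(fixed.sum()), seg_cols, fixed_cols


def group_dxy(aln: HaplotypeAlignment, set1, set2) -> float:
    """Mean pairwise p-distance across all between-set sequence pairs."""
    set1, set2 = list(set1), list(set2)
    if not set1 or not set2:
        raise InputError("both sequence sets must be non-empty")
    m1 = aln.matrix(set1)
    m2 = aln.matrix(set2)
    dists = []
    for i in range(len(set1)):
        for j in range(len(set2)):
            if set1[i] == set2[j]:
                dists.append(0.0)
                continue
            dists.append(p_distance(m1[i], m2[j]))
    return float(np.mean(dists))


def ils_scan(
    aln: HaplotypeAlignment,
    assignment: HaplogroupAssignment,
    outgroup_id: str,
    window_bp: int = 500,
    step_bp: int = 100,
) -> list[tuple[int, int]]:
    """Windows where the haplogroups are further apart than from the outgroup.

    For each window, the incomplete-lineage-sorting flag is
    ``Dxy(A, B) > min(Dxy(A, outgroup), Dxy(B, outgroup))``; overlapping or
    adjacent flagged windows are merged into intervals (0-based half-open
    alignment coordinates).
    """
    if outgroup_id not in aln.ids:
        raise InputError("outgroup not present in alignment")
    if window_bp <= 0 or step_bp <= 0:
        raise ParameterError("window_bp and step_bp must be positive")
    L = aln.length
    window_bp = min(window_bp, L)
    a_ids = assignment.members("A")
    b_ids = assignment.members("B")
    flagged = []
    start = 0
    while start < L:
        end = min(start + window_bp, L)
        sub = aln.slice(start, end)
        try:
            dab = group_dxy(sub, a_ids, b_ids)
            dao = group_dxy(sub, a_ids, [outgroup_id])
            dbo = group_dxy(sub, b_ids, [outgroup_id])
        except InputError:  # window with no comparable sites
            start += step_bp
            continue
        if dab > min(dao, dbo):
            flagged.append((start, end))
        if end == L:
            break
        start += step_bp
    merged: list[list[int]] = []
    for s, e in flagged:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
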