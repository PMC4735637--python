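"""Simulators for every input the mapping/selection pipeline consumes.

Four generators cover the study design end to end:

* :func:`simulate_parental_genomes` — two divergent inbred parental X
  chromosomes (plus an outgroup allele per SNP), optionally carrying a
  "balanced core": a short region of strongly elevated between-line
  divergence decaying into the flanks, emulating a deeply diverged balanced
  polymorphism fixed for opposite alleles in the two lines.
* :func:`simulate_backcross` — a backcross introgression design on the X:
  carrier females crossed to males of the light line for *n* generations,
  with selection retaining only carriers of the dominant dark causal allele;
  crossovers are Poisson with uniform placement, in females only
  (*Drosophila* males are achiasmatic).  Truth ancestry is tracked per
  chromosome copy as intervals.
* :func:`simulate_poolseq` — pooled sequencing of a truth track: per-site
  Poisson depth and binomial sampling of the dark allele, with symmetric
  sequencing error between the two site alleles.
* :func:`simulate_balanced_locus` — a haplotype alignment of a locus where
  two deeply diverged haplogroups segregate, built by infinite-sites
  placement of mutations on a fixed 4-branch genealogy; the outgroup
  attaches inside the ingroup genealogy so that, within the core, it is
  *closer* to one haplogroup than the haplogroups are to each other
  (the incomplete-lineage-sorting signature).

All randomness flows through a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError, ParameterError, SimulationError
from .io import PooledCounts

BASES = np.array(["A", "T", "C", "G"])


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# =====================================================================
# Parental genomes
# =====================================================================

@dataclass
class BalancedCoreConfig:
    """A region of elevated between-line divergence around ``center``.

    Extra fixed differences are planted at per-base density
    ``peak_divergence * exp(-|x - center| / decay_bp)``, mimicking a
    balanced polymorphism whose divergence decays into the flanks.
    """

    center: int
    peak_divergence: float = 0.10
    decay_bp: float = 2000.0

    def validate(self, chrom_length: int):
        if not (0 < self.center <= chrom_length):
            raise ParameterError("core center outside chromosome")
        if not (0 < self.peak_divergence < 1):
            raise ParameterError("peak_divergence must be in (0,1)")
        if self.decay_bp <= 0:
            raise ParameterError("decay_bp must be positive")


@dataclass
class ParentalGenomes:
    """Per-SNP alleles of the dark and light parental lines plus outgroup.

    Three site classes are generated: parental fixed differences
    (dark != light; the within-species polymorphism), outgroup-divergent
    sites (dark == light == ref, outgroup carries the alternative), and
    shared-derived sites (both lines and the outgroup carry the same
    non-reference allele).
    """

    chrom: str
    chrom_length: int
    positions: np.ndarray          # 1-based, strictly increasing
    ref_allele: np.ndarray
    dark_allele: np.ndarray
    light_allele: np.ndarray
    outgroup_allele: np.ndarray
    fixed_diff_mask: np.ndarray    # True iff dark != light
    region_labels: np.ndarray | None = None
    causal_position: int | None = None

    def __post_init__(self):
        n = self.positions.size
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise InputError("SNP positions must be strictly increasing")
        if np.any(self.positions < 1) or np.any(self.positions > self.chrom_length):
            raise InputError("SNP positions outside chromosome")
        if np.any((self.dark_allele != self.light_allele) != self.fixed_diff_mask):
            raise InputError("fixed_diff_mask inconsistent with alleles")

    @property
    def n_snps(self) -> int:
        return int(self.positions.size)

    def site_alleles(self) -> tuple[np.ndarray, np.ndarray]:
        """The two alleles segregating at each site: (dark allele, other).

        Every simulated site is biallelic; the non-dark allele is the light
        allele at fixed differences, the outgroup allele at outgroup-divergent
        sites, and the reference base at shared-derived sites.
        """
        a1 = self.dark_allele
        a2 = np.where(
            self.light_allele != a1,
            self.light_allele,
            np.where(self.outgroup_allele != a1, self.outgroup_allele, self.ref_allele),
        )
        return a1, a2


def _alt_bases(ref: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random base different from ref, per site."""
    ref_idx = np.searchsorted(np.sort(BASES), ref)
    order = np.argsort(BASES)
    # map ref base -> its index in BASES
    idx = order[ref_idx]
    shift = rng.integers(1, 4, size=ref.size)
    return BASES[(idx + shift) % 4]


def simulate_parental_genomes(
    chrom_length: int,
    snp_density: float = 0.02,
    fixed_diff_fraction: float = 0.10,
    seed=None,
    *,
    outgroup_divergent_fraction: float = 0.65,
    core: BalancedCoreConfig | None = None,
    causal_position: int | None = None,
    chrom: str = "X",
) -> ParentalGenomes:
    """Draw the SNP landscape of two inbred parental lines plus outgroup.

    Each base is a SNP independently with probability ``snp_density``; of
    those, ``fixed_diff_fraction`` are parental fixed differences,
    ``outgroup_divergent_fraction`` are outgroup-divergent, and the rest are
    shared-derived.  A fixed-difference SNP is always planted exactly at
    ``causal_position`` when one is given, and extra fixed differences are
    planted around ``core.center`` per :class:`BalancedCoreConfig`.
    """
    if chrom_length <= 0:
        raise ParameterError("chrom_length must be positive")
    if not (0 <= snp_density <= 1):
        raise ParameterError("snp_density must be in [0,1]")
    if not (0 <= fixed_diff_fraction <= 1):
        raise ParameterError("fixed_diff_fraction must be in [0,1]")
    if fixed_diff_fraction + outgroup_divergent_fraction > 1 + 1e-12:
        outgroup_divergent_fraction = 1.0 - fixed_diff_fraction
    rng = _rng(seed)

    mask = rng.random(chrom_length) < snp_density
    positions = np.flatnonzero(mask).astype(np.int64) + 1

    u = rng.random(positions.size)
    is_fixed = u < fixed_diff_fraction
    is_outdiv = (~is_fixed) & (u < fixed_diff_fraction + outgroup_divergent_fraction)

    if core is not None:
        core.validate(chrom_length)
        expected_extra = core.peak_divergence * 2.0 * core.decay_bp
        n_extra = rng.poisson(expected_extra)
        offsets = rng.laplace(0.0, core.decay_bp, size=n_extra)
        extra = np.rint(core.center + offsets).astype(np.int64)
        extra = extra[(extra >= 1) & (extra <= chrom_length)]
        extra = np.setdiff1d(np.unique(extra), positions)
        positions = np.concatenate([positions, extra])
        is_fixed = np.concatenate([is_fixed, np.ones(extra.size, bool)])
        is_outdiv = np.concatenate([is_outdiv, np.zeros(extra.size, bool)])
        order = np.argsort(positions)
        positions, is_fixed, is_outdiv = positions[order], is_fixed[order], is_outdiv[order]

    if causal_position is not None:
        if not (1 <= causal_position <= chrom_length):
            raise ParameterError("causal_position outside chromosome")
        j = np.searchsorted(positions, causal_position)
        if j >= positions.size or positions[j] != causal_position:
            positions = np.insert(positions, j, causal_position)
            is_fixed = np.insert(is_fixed, j, True)
            is_outdiv = np.insert(is_outdiv, j, False)
        else:
            is_fixed[j], is_outdiv[j] = True, False

    n = positions.size
    ref = BASES[rng.integers(0, 4, size=n)]
    alt = _alt_bases(ref, rng)

    dark = ref.copy()
    light = ref.copy()
    outgroup = ref.copy()
    # fixed differences: one line carries the alternative (random orientation);
    # the causal dark allele is by convention the alternative in the dark line
    dark_is_alt = rng.random(n) < 0.5
    if causal_position is not None:
        dark_is_alt[np.searchsorted(positions, causal_position)] = True
    dark[is_fixed & dark_is_alt] = alt[is_fixed & dark_is_alt]
    light[is_fixed & ~dark_is_alt] = alt[is_fixed & ~dark_is_alt]
    # outgroup-divergent: both lines reference, outgroup alternative
    outgroup[is_outdiv] = alt[is_outdiv]
    # shared-derived: all three carry the alternative
    shared = ~is_fixed & ~is_outdiv
    dark[shared] = alt[shared]
    light[shared] = alt[shared]
    outgroup[shared] = alt[shared]

    labels = None
    if core is not None:
        labels = np.where(
            np.abs(positions - core.center) <= 3 * core.decay_bp, "core", "background"
        )

    return ParentalGenomes(
        chrom=chrom,
        chrom_length=int(chrom_length),
        positions=positions,
        ref_allele=ref,
        dark_allele=dark,
        light_allele=light,
        outgroup_allele=outgroup,
        fixed_diff_mask=is_fixed,
        region_labels=labels,
        causal_position=causal_position,
    )


# =====================================================================
# Backcross introgression design
# =====================================================================

@dataclass
class CrossDesign:
    """Parameters of the breeding scheme.

    ``recombination_rate`` is crossovers per Mb per female meiosis
    (0.02 = 2 cM/Mb, a typical *Drosophila* autosome-arm scale).  Males are
    achiasmatic, and in a backcross to the pure light line only females
    transmit recombinant X chromosomes, so recombination is female-only;
    ``chromosome_mode`` is kept for generality but the backcross pedigree
    makes the modes coincide (the paternal chromosome is always pure light).
    """

    causal_position: int
    n_backcross_generations: int = 7
    pool_size: int = 30
    recombination_rate: float = 0.02
    homozygous_line: bool = False
    n_founders: int = 12           # founding X copies of a homozygous line
    selected_sex: str = "female"
    chromosome_mode: str = "X_hemizygous_males"
    max_tries: int = 1000

    def validate(self, chrom_length: int):
        if not (1 <= self.causal_position <= chrom_length):
            raise ParameterError("causal_position outside chromosome")
        if self.n_backcross_generations < 1:
            raise ParameterError("need at least one backcross generation")
        if self.pool_size < 1:
            raise ParameterError("pool_size must be >= 1")
        if self.recombination_rate < 0:
            raise ParameterError("recombination_rate must be >= 0")


@dataclass
class PoolTruth:
    """True ancestry of every chromosome copy in a sequenced pool.

    ``carrier_copies`` are the dark-interval lists (half-open coordinate
    pairs) of the recombinant copies; ``n_light_copies`` intact light-line
    copies complete the pool.  ``fraction`` is the per-SNP true dark-ancestry
    fraction of the pool.
    """

    chrom_length: int
    positions: np.ndarray
    carrier_copies: list[list[tuple[float, float]]]
    n_light_copies: int
    fraction: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.fraction is None:
            self.fraction = self._compute_fraction(self.positions)

    @property
    def n_copies(self) -> int:
        return len(self.carrier_copies) + self.n_light_copies

    def _compute_fraction(self, positions: np.ndarray) -> np.ndarray:
        dark = np.zeros(positions.size, dtype=np.int64)
        for intervals in self.carrier_copies:
            dark += _membership(intervals, positions)
        return dark / self.n_copies

    def carrier_fraction(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Mean dark-ancestry among recombinant (carrier-lineage) copies only."""
        positions = self.positions if positions is None else positions
        dark = np.zeros(positions.size, dtype=np.int64)
        for intervals in self.carrier_copies:
            dark += _membership(intervals, positions)
        return dark / len(self.carrier_copies)

    def truth_intervals(self) -> list[tuple[int, float, float]]:
        """(copy index, start, end) dark intervals for BED export."""
        out = []
        for i, intervals in enumerate(self.carrier_copies):
            for s, e in intervals:
                out.append((i, s, e))
        return out


def _membership(intervals, positions) -> np.ndarray:
    """1 where a position falls inside a disjoint sorted interval list."""
    if not intervals:
        return np.zeros(positions.size, dtype=np.int64)
    edges = np.asarray(intervals, dtype=float).ravel()
    idx = np.searchsorted(edges, positions, side="right")
    return (idx % 2).astype(np.int64)


def _intersect(a, b):
    """Intersection of two disjoint sorted interval lists."""
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _contains(intervals, pos) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _maternal_segments(length: float, lam: float, rng) -> list[tuple[float, float]]:
    """Segments of a gamete copied from the maternal (carrier) homolog.

    Crossover count is Poisson(lam); positions are uniform (no interference);
    the starting homolog is a fair coin.
    """
    k = rng.poisson(lam)
    cuts = np.sort(rng.uniform(0.0, length, size=k)) if k else np.array([])
    bounds = np.concatenate([[0.0], cuts, [length]])
    phase = rng.integers(0, 2)
    return [
        (bounds[i], bounds[i + 1])
        for i in range(len(bounds) - 1)
        if (i + phase) % 2 == 0 and bounds[i] < bounds[i + 1]
    ]


def _carrier_gamete(chrom_length, lam, causal, n_gens, rng, max_tries):
    """One dark-carrier gamete after ``n_gens`` backcrosses with selection.

    Each generation the carrier female's recombinant gamete is conditioned
    (by rejection) on carrying the dark allele at the causal position: this
    is exactly selection of dark offspring under complete dominance.
    """
    dark = [(0.0, float(chrom_length))]
    for _ in range(n_gens):
        for _try in range(max_tries):
            segs = _maternal_segments(float(chrom_length), lam, rng)
            gam = _intersect(dark, segs)
            if _contains(gam, float(causal)):
                dark = gam
                break
        else:
            raise SimulationError(
                "selection retained no dark carriers within the retry budget; "
                "check causal_position and recombination_rate"
            )
    return dark


def simulate_backcross(
    parents: ParentalGenomes, design: CrossDesign, seed=None
) -> PoolTruth:
    """Simulate the introgression design and return pool truth ancestry.

    Heterozygous pool (default): ``pool_size`` females, each carrying one
    recombinant dark-carrier X (``n_backcross_generations`` meioses under
    selection) and one intact light X.

    Homozygous line (``design.homozygous_line``): ``n_founders`` independent
    carrier gametes found the line (sibling intercross with selection of
    dark homozygotes); the pooled females' ``2 * pool_size`` copies are drawn
    with replacement from the founders, all dark at the causal position.
    """
    design.validate(parents.chrom_length)
    rng = _rng(seed)
    lam = design.recombination_rate * parents.chrom_length / 1e6

    if design.homozygous_line:
        founders = [
            _carrier_gamete(parents.chrom_length, lam, design.causal_position,
                            design.n_backcross_generations, rng, design.max_tries)
            for _ in range(design.n_founders)
        ]
        picks = rng.integers(0, design.n_founders, size=2 * design.pool_size)
        copies = [founders[i] for i in picks]
        return PoolTruth(parents.chrom_length, parents.positions, copies, 0)

    copies = [
        _carrier_gamete(parents.chrom_length, lam, design.causal_position,
                        design.n_backcross_generations, rng, design.max_tries)
        for _ in range(design.pool_size)
    ]
    return PoolTruth(parents.chrom_length, parents.positions, copies,
                     n_light_copies=design.pool_size)


def expected_carrier_ancestry(distance_bp, recombination_rate, n_generations):
    """Closed-form dark-ancestry probability on a carrier gamete.

    For a neutral locus at ``distance_bp`` from the causal position, the
    per-meiosis recombination fraction r follows Haldane's map function
    (Morgans = rate/Mb x Mb), and after n selected backcross meioses the
    carrier gamete is dark at the locus with probability ``(1 - r)**n``
    (0.5**n when unlinked, 1 at the causal site).
    """
    morgans = np.asarray(distance_bp, dtype=float) * recombination_rate / 1e6
    r = 0.5 * (1.0 - np.exp(-2.0 * morgans))
    return (1.0 - r) ** n_generations


# =====================================================================
# Pooled sequencing
# =====================================================================

def simulate_poolseq(
    pool_truth,
    mean_depth: float,
    error_rate: float = 0.0,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequence a pool: per-site depth ~ Poisson, dark reads ~ Binomial.

    ``pool_truth`` may be a :class:`PoolTruth` or a bare per-site truth
    fraction array.  Sequencing error flips reads symmetrically between the
    two site alleles, so the sampled dark-read probability is
    ``f (1 - e) + (1 - f) e``.  Returns ``(dark_reads, depth)``.
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    if not (0 <= error_rate < 0.5):
        raise ParameterError("error_rate must be in [0, 0.5)")
    rng = _rng(seed)
    frac = pool_truth.fraction if isinstance(pool_truth, PoolTruth) else np.asarray(pool_truth, float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise InputError("truth fraction must be in [0,1]")
    depth = rng.poisson(mean_depth, size=frac.size)
    p = frac * (1 - error_rate) + (1 - frac) * error_rate
    dark = rng.binomial(depth, p)
    return dark, depth


def counts_from_reads(
    parents: ParentalGenomes, dark_reads: np.ndarray, depth: np.ndarray
) -> np.ndarray:
    """Scatter (dark, other) read counts into sync base columns (n, 6)."""
    a1, a2 = parents.site_alleles()
    n = parents.n_snps
    arr = np.zeros((n, 6), dtype=np.int64)
    base_idx = {"A": 0, "T": 1, "C": 2, "G": 3}
    i1 = np.array([base_idx[b] for b in a1])
    i2 = np.array([base_idx[b] for b in a2])
    rows = np.arange(n)
    np.add.at(arr, (rows, i1), dark_reads)
    np.add.at(arr, (rows, i2), depth - dark_reads)
    return arr


def simulate_experiment_counts(
    parents: ParentalGenomes,
    pools: dict[str, tuple[object, float]],
    error_rate: float = 0.0,
    seed=None,
) -> PooledCounts:
    """Pool-sequence several samples onto one sync-style counts table.

    ``pools`` maps sample name to ``(truth, mean_depth)`` where truth is a
    :class:`PoolTruth` or a per-site dark-allele fraction array.
    """
    rng = _rng(seed)
    samples = {}
    for name, (truth, depth) in pools.items():
        dark, dep = simulate_poolseq(truth, depth, error_rate, rng)
        samples[name] = counts_from_reads(parents, dark, dep)
    return PooledCounts(
        chrom=parents.chrom,
        positions=parents.positions,
        ref=parents.ref_allele,
        samples=samples,
    )


def line_truth_fractions(parents: ParentalGenomes) -> dict[str, np.ndarray]:
    """Dark-allele truth fractions of the fixed lines and the outgroup.

    The dark line is fixed for the dark allele everywhere; the light line
    shares it except at parental fixed differences; the outgroup carries it
    wherever its allele coincides with the dark line's.
    """
    return {
        "dark": np.ones(parents.n_snps),
        "light": (~parents.fixed_diff_mask).astype(float),
        "outgroup": (parents.outgroup_allele == parents.dark_allele).astype(float),
    }


# =====================================================================
# Balanced-polymorphism haplotype alignment
# =====================================================================

@dataclass
class BalancedLocusConfig:
    """Parameters of the two-haplogroup balanced locus.

    Divergences are substitutions/site.  Inside ``core_interval`` (0-based
    half-open alignment coordinates) the between-haplogroup divergence is
    ``between_divergence``; it decays to the within-group background over
    ``flank_decay`` bases outside the core.  ``outgroup_divergence`` is the
    core distance between the outgroup and its *closer* haplogroup (group A)
    and must be below ``between_divergence`` — the incomplete-lineage-sorting
    signature.
    """

    locus_length: int = 3000
    core_interval: tuple[int, int] = (1250, 1750)
    n_per_haplogroup: int = 18
    between_divergence: float = 0.07
    within_diversity: float = 0.005
    outgroup_divergence: float = 0.05
    flank_decay: float = 500.0
    outgroup_gap_length: int = 0

    def validate(self):
        s, e = self.core_interval
        if not (0 <= s < e <= self.locus_length):
            raise ParameterError("core_interval outside locus")
        if self.n_per_haplogroup < 2:
            raise ParameterError("need >= 2 haplotypes per haplogroup")
        if not (0 <= self.within_diversity <= self.between_divergence):
            raise ParameterError("need 0 <= within <= between divergence")
        if self.between_divergence > 0 and not (
            self.outgroup_divergence < self.between_divergence
            or self.between_divergence == self.within_diversity
        ):
            raise ParameterError(
                "outgroup_divergence must be below between_divergence in the core"
            )
        if self.flank_decay <= 0:
            raise ParameterError("flank_decay must be positive")
        # branch-length decomposition must be realisable
        a0 = (self.between_divergence - self.within_diversity) / 4.0
        if self.outgroup_divergence - self.within_diversity / 2.0 - a0 < -1e-12:
            raise ParameterError(
                "outgroup_divergence too small for the requested between/within split"
            )


def simulate_balanced_locus(config: BalancedLocusConfig, seed=None):
    """Generate a haplotype alignment with two balanced haplogroups.

    Mutations are placed site by site (infinite sites: at most one per
    column) on a fixed genealogy: tip branches carry the within-group
    diversity; stem branches of haplogroups A and B carry the between-group
    excess; the outgroup attaches to the A stem, making it closer to A than
    A is to B wherever the stems are at full (core) length.  Outside the
    core all group-defining branch lengths decay as exp(-distance/flank_decay),
    leaving the haplogroups statistically exchangeable in the far flanks
    while the outgroup stays at its background species divergence.
    """
    from .haplotype_popgen import HaplotypeAlignment

    config.validate()
    rng = _rng(seed)
    L = config.locus_length
    nA = nB = config.n_per_haplogroup
    w, dAB, dOA = (config.within_diversity, config.between_divergence,
                   config.outgroup_divergence)

    pos = np.arange(L)
    s, e = config.core_interval
    dist = np.maximum(0, np.maximum(s - pos, pos - (e - 1)))
    g = np.exp(-dist / config.flank_decay)

    t = w / 2.0                       # per-tip branch length
    a0 = (dAB - w) / 4.0              # haplogroup stem (each)
    ex0 = (dAB - w) / 2.0             # shared ingroup branch below the root
    eO0 = max(dOA - w / 2.0 - a0, 0.0)  # outgroup branch (incl. its tip)

    p_tip = (nA + nB) * t
    c1 = np.full(L, p_tip)
    c2 = c1 + a0 * g                  # A stem
    c3 = c2 + a0 * g                  # B stem
    c4 = c3 + ex0 * g                 # shared ingroup vs outgroup
    c5 = c4 + eO0                     # outgroup branch
    if np.any(c5 > 1.0):
        raise ParameterError("total per-site mutation probability exceeds 1")

    u = rng.random(L)
    anc_idx = rng.integers(0, 4, size=L)
    derived_idx = (anc_idx + rng.integers(1, 4, size=L)) % 4
    anc, der = BASES[anc_idx], BASES[derived_idx]

    n_rows = nA + nB + 1
    out_row = n_rows - 1
    seqs = np.tile(anc, (n_rows, 1))

    category = np.zeros(L, dtype="<U12")
    category[:] = "invariant"

    tip_hit = u < c1
    tip_idx = np.minimum((u / t).astype(int), nA + nB - 1) if t > 0 else None
    if t > 0:
        cols = np.flatnonzero(tip_hit)
        seqs[tip_idx[cols], cols] = der[cols]
        category[cols] = "singleton"

    # the deep branch (c3..c4) subtends haplogroup A together with the
    # outgroup: the ((A, outgroup), B) topology that makes the outgroup
    # closer to A than A is to B inside the core
    for lo, hi, rows, label in (
        (c1, c2, slice(0, nA), "fixed_A"),
        (c2, c3, slice(nA, nA + nB), "fixed_B"),
        (c3, c4, np.r_[0:nA, out_row], "AO_shared"),
        (c4, c5, slice(out_row, out_row + 1), "outgroup"),
    ):
        cols = np.flatnonzero((u >= lo) & (u < hi))
        if isinstance(rows, slice):
            seqs[rows, cols] = der[cols]
        else:
            seqs[np.ix_(rows, cols)] = der[cols]
        category[cols] = label

    if config.outgroup_gap_length > 0:
        mid = (s + e) // 2
        g0 = max(0, mid - config.outgroup_gap_length // 2)
        seqs[out_row, g0:g0 + config.outgroup_gap_length] = "-"

    ids = (
        [f"dark_{i + 1:02d}" for i in range(nA)]
        + [f"light_{i + 1:02d}" for i in range(nB)]
        + ["outgroup"]
    )
    populations = {
        sid: ("cameroon" if i % 2 == 0 else "gabon")
        for i, sid in enumerate(ids[:-1])
    }
    truth = {
        "category": category,
        "group_of": {sid: ("A" if sid.startswith("dark") else "B") for sid in ids[:-1]},
        "config": replace(config),
    }
    return HaplotypeAlignment(
        ids=ids,
        seqs=seqs,
        populations=populations,
        outgroup_id="outgroup",
        subregion=config.core_interval,
        site_truth=truth,
    )
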