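"""Mapping the causal locus from pooled allele counts.

The chain is: call diagnostic SNPs (alleles fixed in the dark parental line
and absent in the light line, minimum count in every line), compute the
per-SNP dark-ancestry proportion of each introgression pool, average within
non-overlapping 100-kb windows, drop windows that look identical-by-descent
between the parental strains, and call candidate windows whose combined
BC-heterozygous/homozygous score sits near the 75% expectation.  A simple
goodness-of-fit test checks the 1:1 F2 segregation expected of a single
X-linked locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError
from .io import PooledCounts


@dataclass
class DiagnosticSnps:
    """SNPs carrying an allele fixed in the dark line and absent in the light.

    ``dark_base`` is the diagnostic (dark-line) allele per retained SNP.
    """

    positions: np.ndarray
    dark_base: np.ndarray
    index: np.ndarray  # row index into the source PooledCounts

    @property
    def n(self) -> int:
        return int(self.positions.size)


def call_diagnostic_snps(
    counts: PooledCounts,
    dark: str = "dark",
    light: str = "light",
    min_count: int = 10,
) -> DiagnosticSnps:
    """Select diagnostic SNPs from a multi-sample counts table.

    A site is retained iff it is diallelic across all samples (exactly two
    bases with nonzero total count), the total count is at least
    ``min_count`` in *every* sample, and one of the two alleles accounts for
    the whole dark-line count while being absent from the light line.
    """
    if dark not in counts.samples or light not in counts.samples:
        raise InputError(f"samples {dark!r} and {light!r} must both be present")

    total = np.zeros((counts.n_sites, 6), dtype=np.int64)
    for arr in counts.samples.values():
        total += arr
    base_total = total[:, :4]  # A,T,C,G; N/del never count as alleles
    diallelic = (base_total > 0).sum(axis=1) == 2

    ok_depth = np.ones(counts.n_sites, dtype=bool)
    for arr in counts.samples.values():
        ok_depth &= arr.sum(axis=1) >= min_count

    dark_arr = counts.samples[dark][:, :4]
    light_arr = counts.samples[light][:, :4]
    dark_depth = dark_arr.sum(axis=1)
    # the diagnostic allele: full dark count, zero light count
    fixed_in_dark = dark_arr == dark_depth[:, None]
    absent_in_light = light_arr == 0
    candidate = fixed_in_dark & absent_in_light & (base_total > 0)
    has_diag = candidate.any(axis=1)
    keep = diallelic & ok_depth & has_diag & (dark_depth > 0)

    base_idx = np.argmax(candidate[keep], axis=1)
    bases = np.array(["A", "T", "C", "G"])[base_idx]
    idx = np.flatnonzero(keep)
    return DiagnosticSnps(positions=counts.positions[idx], dark_base=bases, index=idx)


def snp_ancestry(
    counts: PooledCounts, pool: str, diagnostic: DiagnosticSnps
) -> np.ndarray:
    """Per-SNP dark-ancestry proportion of a pool at the diagnostic SNPs.

    The proportion of reads carrying the diagnostic allele; NaN where the
    pool has zero depth.
    """
    if diagnostic.n == 0:
        raise InputError("diagnostic SNP set is empty")
    arr = counts.samples[pool][diagnostic.index]
    depth = arr.sum(axis=1).astype(float)
    dark_reads = np.array(
        [arr[i, "ATCG".index(b)] for i, b in enumerate(diagnostic.dark_base)],
        dtype=float,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(depth > 0, dark_reads / depth, np.nan)
    return prop


def window_average(
    values: np.ndarray,
    positions: np.ndarray,
    width: int = 100_000,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Average per-SNP values over a fixed tiling of windows.

    Windows tile the chromosome from coordinate 1 (1-based inclusive ends):
    [1, width], [width+1, 2*width], ...  NaN values are ignored; windows
    without any (non-missing) SNP get a NaN mean, never zero.
    """
    if width <= 0:
        raise ParameterError("window width must be positive")
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    if positions.size != values.size:
        raise InputError("values and positions must have equal length")
    if positions.size > 1 and np.any(np.diff(positions) < 0):
        raise InputError("positions must be sorted")

    last = chrom_length if chrom_length is not None else (
        int(positions.max()) if positions.size else width
    )
    n_windows = max(1, -(-int(last) // width))
    win = (positions - 1) // width
    valid = ~np.isnan(values)
    sums = np.bincount(win[valid], weights=values[valid], minlength=n_windows)
    counts = np.bincount(win[valid], minlength=n_windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    starts = np.arange(n_windows, dtype=np.int64) * width + 1
    return pd.DataFrame(
        {
            "start": starts,
            "end": starts + width - 1,
            "n_snps": counts.astype(np.int64),
            "mean": means,
        }
    )


def ibd_filter(
    fixed_diff_count: np.ndarray,
    window_sites: np.ndarray | int,
    threshold: float = 1e-3,
) -> np.ndarray:
    """Flag windows that look identical-by-descent between the parents.

    A window is excluded iff its parental fixed-difference density is
    strictly below ``threshold`` (default 1 per 1000 sites); a window at
    exactly the threshold is retained.
    """
    fixed_diff_count = np.asarray(fixed_diff_count, dtype=float)
    sites = np.broadcast_to(np.asarray(window_sites, dtype=float), fixed_diff_count.shape)
    if np.any(sites <= 0):
        raise ParameterError("window site counts must be positive")
    return (fixed_diff_count / sites) < threshold


def parental_fixed_diff_windows(
    counts: PooledCounts,
    dark: str = "dark",
    light: str = "light",
    width: int = 100_000,
    chrom_length: int | None = None,
    min_coverage: int = 2,
) -> pd.DataFrame:
    """Count apparent parental fixed differences per tiling window.

    A site counts as a fixed difference when each line's reads are all one
    base (coverage >= ``min_coverage``) and the two bases differ.
    """
    d = counts.samples[dark][:, :4]
    l = counts.samples[light][:, :4]
    ddep, ldep = d.sum(axis=1), l.sum(axis=1)
    dmax, lmax = d.argmax(axis=1), l.argmax(axis=1)
    fixed = (
        (ddep >= min_coverage)
        & (ldep >= min_coverage)
        & (d.max(axis=1) == ddep)
        & (l.max(axis=1) == ldep)
        & (dmax != lmax)
    )
    tab = window_average(fixed.astype(float), counts.positions, width, chrom_length)
    tab = tab.rename(columns={"mean": "fixed_frac"})
    tab["fixed_diffs"] = (tab["fixed_frac"].fillna(0) * tab["n_snps"]).round().astype(int)
    return tab


def candidate_windows(
    bc7_means: np.ndarray,
    nn_means: np.ndarray,
    excluded: np.ndarray,
    starts: np.ndarray,
    width: int = 100_000,
    center: float = 0.75,
    band: float = 0.05,
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Score windows against the 75% expectation and call candidate runs.

    The combined score of a retained window is the mean of the two pools'
    window means (heterozygous backcross expected at 50%, homozygous line at
    100%, so the causal window scores near 75%).  Candidates are maximal
    runs of retained windows with ``|score - center| <= band``, and windows
    are ranked by ``|score - center|`` ascending.  Excluded or empty windows
    carry no score.
    """
    bc7 = np.asarray(bc7_means, dtype=float)
    nn = np.asarray(nn_means, dtype=float)
    excluded = np.asarray(excluded, dtype=bool)
    if not (bc7.shape == nn.shape == excluded.shape):
        raise InputError("window tables are not aligned")
    starts = np.asarray(starts, dtype=np.int64)

    score = (bc7 + nn) / 2.0
    score[excluded] = np.nan
    dev = np.abs(score - center)
    is_cand = ~np.isnan(score) & (dev <= band)

    tab = pd.DataFrame(
        {
            "start": starts,
            "end": starts + width - 1,
            "bc7_mean": bc7,
            "nn_mean": nn,
            "score": score,
            "ibd_excluded": excluded,
            "candidate": is_cand,
        }
    )
    order = np.argsort(np.where(np.isnan(dev), np.inf, dev), kind="stable")
    rank = np.full(len(tab), -1, dtype=int)
    rank[order[is_cand[order]]] = np.arange(int(is_cand.sum()))
    tab["rank"] = np.where(rank >= 0, rank, np.nan)

    intervals = []
    i, n = 0, len(tab)
    while i < n:
        if is_cand[i]:
            j = i
            while j + 1 < n and is_cand[j + 1]:
                j += 1
            intervals.append((int(starts[i]), int(starts[j]) + width - 1))
            i = j + 1
        else:
            i += 1
    if not is_cand.any():
        import warnings

        warnings.warn("no candidate windows (all excluded or out of band)", stacklevel=2)
    return tab, intervals


def segregation_test(n_class1: int, n_class2: int) -> tuple[float, float]:
    """Goodness-of-fit chi-square against a 1:1 segregation ratio (1 df)."""
    if n_class1 < 0 or n_class2 < 0:
        raise InputError("counts must be non-negative")
    if n_class1 == 0 and n_class2 == 0:
        raise InputError("counts must not both be zero")
    chi2, p = stats.chisquare([n_class1, n_class2])
    return float(chi2), float(p)
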