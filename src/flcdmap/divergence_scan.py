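"""Per-SNP Dxy between two lines and SNP-indexed sliding-window smoothing.

For each diallelic SNP with minimum coverage in both lines, per-SNP
divergence between lines 1 and 2 is

    Dxy = p1 * q2 + p2 * q1,      q = 1 - p,

where p is the frequency of the allele matching the reference genome in
each line.  Smoothing averages Dxy over each SNP +/- ``half_width`` SNPs
(501-SNP windows by default); windows shrink at chromosome ends so every
SNP gets a value, with a flag marking truncated windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .io import PooledCounts


def allele_frequencies(
    counts: PooledCounts, sample: str, min_coverage: int = 2
) -> np.ndarray:
    """Frequency of the reference-matching allele per site for one sample.

    NaN where coverage (A+T+C+G reads) is below ``min_coverage``.
    """
    arr = counts.samples[sample][:, :4].astype(float)
    depth = arr.sum(axis=1)
    ref_reads = counts.base_count(sample, counts.ref).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(depth >= min_coverage, ref_reads / depth, np.nan)
    return p


def snp_dxy(p1, p2):
    """Per-SNP between-line divergence ``p1*q2 + p2*q1``; symmetric, in [0,1]."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    for p in (p1, p2):
        bad = (p < -1e-12) | (p > 1 + 1e-12)
        if np.any(bad & ~np.isnan(p)):
            raise InputError("allele frequencies must be in [0,1]")
    return p1 * (1 - p2) + (1 - p1) * p2


def sliding_mean(values: np.ndarray, half_width: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values`` over indices [i-half_width, i+half_width].

    Windows are truncated at the ends of the vector (never padded, never
    dropped).  Returns ``(smoothed, truncated_flag)``.
    """
    if half_width < 0:
        raise ParameterError("half_width must be >= 0")
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return v.copy(), np.zeros(0, dtype=bool)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_width, 0)
    hi = np.minimum(idx + half_width, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    truncated = (idx < half_width) | (idx > n - 1 - half_width)
    return smoothed, truncated


def sliding_dxy(
    dxy: np.ndarray, positions: np.ndarray, half_width: int = 250
) -> pd.DataFrame:
    """SNP-indexed sliding-window average Dxy (501-SNP windows by default).

    SNPs with missing Dxy (coverage filter) are dropped before indexing, so
    windows always span ``2*half_width + 1`` retained SNPs away from the
    chromosome ends.
    """
    dxy = np.asarray(dxy, dtype=float)
    positions = np.asarray(positions)
    if positions.size != dxy.size:
        raise InputError("dxy and positions must have equal length")
    if positions.size > 1 and np.any(np.diff(positions) < 0):
        raise InputError("positions must be sorted")
    keep = ~np.isnan(dxy)
    pos, val = positions[keep], dxy[keep]
    smoothed, truncated = sliding_mean(val, half_width)
    return pd.DataFrame(
        {"pos": pos, "dxy": val, "smoothed": smoothed, "truncated": truncated}
    )


def peak_interval(
    smoothed: np.ndarray,
    positions: np.ndarray,
    threshold_multiplier: float = 5.0,
) -> list[tuple[int, int]]:
    """Intervals where smoothed divergence exceeds a multiple of the median.

    Runs of consecutive above-threshold SNPs are merged into one interval
    (1-based inclusive coordinates of the first and last SNP of the run).
    """
    smoothed = np.asarray(smoothed, dtype=float)
    positions = np.asarray(positions)
    if smoothed.size == 0:
        return []
    med = float(np.nanmedian(smoothed))
    above = smoothed > threshold_multiplier * med
    intervals = []
    i, n = 0, above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            intervals.append((int(positions[i]), int(positions[j])))
            i = j + 1
        else:
            i += 1
    return intervals
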