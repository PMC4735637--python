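"""Calibrated distance-based divergence-time estimation.

A strict molecular clock interpolates the age of a split linearly in
(Jukes-Cantor corrected) sequence distance:

    age(A, B) = calibration_age * d(A, B) / d(calibration split)

with d the mean between-clade corrected p-distance.  The default
calibration is the most recent common ancestor of the clade containing the
analysed taxa, set to 11 million years for the melanogaster species
subgroup.  Uncertainty comes from site bootstrap: alignment columns are
resampled with replacement and the age ratio recomputed.  This is a
deterministic, transparent stand-in for full Bayesian (e.g. HKY+I MCMC)
dating; agreement is expected on the scale of the estimates, not to the
posterior decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .haplotype_popgen import HaplotypeAlignment

_VALID = ("A", "C", "G", "T")


def jc_correct(p):
    """Jukes-Cantor corrected distance ``-(3/4) ln(1 - 4p/3)``.

    Defined for p < 0.75; always >= p.  Raises at or beyond saturation.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise InputError("p-distance must be non-negative")
    if np.any(p >= 0.75):
        raise ParameterError("p-distance at or beyond Jukes-Cantor saturation (0.75)")
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    return float(d) if d.ndim == 0 else d


def age_from_distances(d_split: float, d_calibration: float, calibration_age: float) -> float:
    """Linear-clock age; scale-equivariant (d -> c*d leaves the age fixed)."""
    if d_calibration <= 0:
        raise InputError("calibration distance is zero: dating undefined")
    return calibration_age * d_split / d_calibration


@dataclass
class ClockCalibration:
    """A calibrated split: two taxon sets whose divergence has a known age.

    ``corrected`` selects Jukes-Cantor correction of p-distances (on by
    default); the calibration clade should span the root of the analysed
    taxa so that every dated split is nested inside it.
    """

    group1: tuple[str, ...]
    group2: tuple[str, ...]
    age_mya: float = 11.0
    corrected: bool = True

    def __post_init__(self):
        self.group1 = tuple(self.group1)
        self.group2 = tuple(self.group2)
        if self.age_mya <= 0:
            raise ParameterError("calibration_age must be positive")
        if not self.group1 or not self.group2:
            raise ParameterError("calibration groups must be non-empty")


@dataclass
class DateEstimate:
    age_mya: float
    ci_low: float
    ci_high: float
    sd: float
    d_split: float
    d_calibration: float
    n_boot: int
    seed: int | None


def _pair_tables(aln: HaplotypeAlignment, pairs) -> tuple[np.ndarray, np.ndarray]:
    """Per-column difference and comparability indicators for a pair list."""
    L = aln.length
    diffs = np.zeros((len(pairs), L), dtype=np.float32)
    valids = np.zeros((len(pairs), L), dtype=np.float32)
    for k, (i, j) in enumerate(pairs):
        a, b = aln.row(i), aln.row(j)
        valid = np.isin(a, _VALID) & np.isin(b, _VALID)
        diffs[k] = valid & (a != b)
        valids[k] = valid
    return diffs, valids


def _mean_corrected(diffs, valids, weights, corrected: bool, strict=False) -> np.ndarray:
    """Mean (corrected) distance over pairs, per bootstrap column weighting."""
    nd = diffs @ weights
    nv = valids @ weights
    if np.any(nv == 0):
        raise InputError("a sequence pair has no comparable sites in a resample")
    p = nd / nv
    if corrected:
        if strict and np.any(p >= 0.75):
            raise ParameterError("pairwise distance beyond Jukes-Cantor saturation")
        p = np.minimum(p, 0.7499)  # bootstrap resamples may graze saturation
        p = -0.75 * np.log1p(-4.0 * p / 3.0)
    return p.mean(axis=0)


def date_split(
    aln: HaplotypeAlignment,
    clade_a,
    clade_b,
    calibration: ClockCalibration,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DateEstimate:
    """Date the split between two clades against a calibrated split.

    The point estimate uses the full alignment; the confidence interval is
    the 2.5-97.5 percentile range of the age over ``n_boot`` site
    bootstraps (columns resampled with replacement, seeded).
    """
    clade_a, clade_b = list(clade_a), list(clade_b)
    for ids, what in ((clade_a, "clade_a"), (clade_b, "clade_b"),
                      (calibration.group1, "calibration"), (calibration.group2, "calibration")):
        missing = set(ids) - set(aln.ids)
        if missing:
            raise InputError(f"{what}: taxa {sorted(missing)} not in alignment")
    split_pairs = [(i, j) for i in clade_a for j in clade_b]
    cal_pairs = [(i, j) for i in calibration.group1 for j in calibration.group2]

    sd_, sv_ = _pair_tables(aln, split_pairs)
    cd_, cv_ = _pair_tables(aln, cal_pairs)
    L = aln.length
    ones = np.ones((L, 1), dtype=np.float32)
    d_split = float(_mean_corrected(sd_, sv_, ones, calibration.corrected, strict=True)[0])
    d_cal = float(_mean_corrected(cd_, cv_, ones, calibration.corrected, strict=True)[0])
    age = age_from_distances(d_split, d_cal, calibration.age_mya)

    rng = np.random.default_rng(seed)
    if n_boot > 0:
        w = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot).T.astype(np.float32)
        bs = _mean_corrected(sd_, sv_, w, calibration.corrected)
        bc = _mean_corrected(cd_, cv_, w, calibration.corrected)
        good = bc > 0
        ages = calibration.age_mya * bs[good] / bc[good]
        lo, hi = np.percentile(ages, [2.5, 97.5])
        sd = float(ages.std(ddof=1))
    else:
        lo = hi = age
        sd = float("nan")
    return DateEstimate(
        age_mya=float(age),
        ci_low=float(lo),
        ci_high=float(hi),
        sd=sd,
        d_split=d_split,
        d_calibration=d_cal,
        n_boot=n_boot,
        seed=seed,
    )
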