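"""HKA-like tests: excess polymorphism relative to divergence.

Sites are classified from line allele frequencies and the outgroup:

* polymorphic — Dxy > 0 between the light and dark parental lines;
* divergent  — Dxy = 1 between both lines and the outgroup (the two lines
  fixed for the same allele, the outgroup fixed for the other);
* other      — everything else, including sites with missing data.

The windowed test compares observed polymorphic/divergent counts in each
SNP +/- 50 classified SNPs (101-SNP windows) to expectations from the
chromosome-wide class proportions, with a chi-square at 1 df.  The
locus-level test is a plain 2x2 contingency chi-square (locus x class,
1 df, no continuity correction) on per-locus counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError
from .divergence_scan import sliding_mean, snp_dxy

OTHER, POLYMORPHIC, DIVERGENT = 0, 1, 2


@dataclass
class LocusCounts:
    """Polymorphic and divergent SNP tallies for one sequenced locus."""

    name: str
    n_polymorphic: int
    n_divergent: int
    length: int | None = None

    def __post_init__(self):
        if self.n_polymorphic < 0 or self.n_divergent < 0:
            raise InputError("locus counts must be non-negative")


def classify_sites(p1, p2, p_out) -> np.ndarray:
    """Classify sites as polymorphic / divergent / other (codes 1 / 2 / 0).

    Frequencies are of the reference-matching allele (NaN = missing, e.g.
    no outgroup coverage at the site, which forces class "other").
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p_out = np.asarray(p_out, dtype=float)
    if not (p1.shape == p2.shape == p_out.shape):
        raise InputError("frequency arrays must share coordinates")

    d12 = snp_dxy(p1, p2)
    with np.errstate(invalid="ignore"):
        d1o = snp_dxy(p1, p_out)
        d2o = snp_dxy(p2, p_out)
        poly = d12 > 0
        div = (d1o == 1.0) & (d2o == 1.0)
    codes = np.zeros(p1.shape, dtype=np.int8)
    ok12 = ~np.isnan(d12)
    codes[ok12 & poly] = POLYMORPHIC
    ok_out = ok12 & ~np.isnan(d1o) & ~np.isnan(d2o)
    codes[ok_out & div & ~poly] = DIVERGENT
    return codes


def hka_chi2(n_poly, n_div, expected_poly_fraction) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square (1 df) of observed class counts against expected fractions."""
    n_poly = np.asarray(n_poly, dtype=float)
    n_div = np.asarray(n_div, dtype=float)
    total = n_poly + n_div
    e_poly = total * expected_poly_fraction
    e_div = total * (1.0 - expected_poly_fraction)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (n_poly - e_poly) ** 2 / e_poly + (n_div - e_div) ** 2 / e_div
        p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def window_hka(
    codes: np.ndarray,
    positions: np.ndarray,
    half_width: int = 50,
) -> pd.DataFrame:
    """Sliding-window HKA-like chi-square over the classified SNPs.

    Windows are indexed over polymorphic/divergent SNPs only (class "other"
    is dropped before indexing); expected counts come from chromosome-wide
    class proportions.  A Bonferroni-adjusted p is emitted as a convenience
    column but plays no role in any call.
    """
    codes = np.asarray(codes)
    positions = np.asarray(positions)
    if codes.shape != positions.shape:
        raise InputError("codes and positions must have equal length")
    keep = codes != OTHER
    pos = positions[keep]
    is_poly = (codes[keep] == POLYMORPHIC).astype(float)
    n = pos.size
    if n == 0:
        raise InputError("no classified SNPs")
    global_poly = float(is_poly.mean())
    if global_poly in (0.0, 1.0):
        raise InputError("need both site classes chromosome-wide")

    mean_poly, truncated = sliding_mean(is_poly, half_width)
    idx = np.arange(n)
    width = np.minimum(idx + half_width, n - 1) - np.maximum(idx - half_width, 0) + 1
    n_poly = np.rint(mean_poly * width)
    n_div = width - n_poly
    chi2, p = hka_chi2(n_poly, n_div, global_poly)
    n_windows = n
    return pd.DataFrame(
        {
            "pos": pos,
            "n_poly": n_poly.astype(int),
            "n_div": n_div.astype(int),
            "chi2": chi2,
            "p": p,
            "p_bonferroni": np.minimum(p * n_windows, 1.0),
            "truncated": truncated,
        }
    )


def locus_hka(focal: LocusCounts, reference: LocusCounts) -> tuple[float, float]:
    """2x2 contingency chi-square (locus x {polymorphic, divergent}), 1 df.

    No continuity correction.  A zero marginal (both loci lacking one class,
    or an empty locus) makes the statistic undefined: returns (nan, nan).
    """
    table = np.array(
        [
            [focal.n_polymorphic, focal.n_divergent],
            [reference.n_polymorphic, reference.n_divergent],
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        import warnings

        warnings.warn("degenerate 2x2 table: chi-square undefined", stacklevel=2)
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def read_locus_counts(path) -> list[LocusCounts]:
    """Read per-locus tallies from a small TSV (name, n_polymorphic,
    n_divergent[, length])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "n_polymorphic", "n_divergent"}
    if not required.issubset(df.columns):
        raise ParameterError(f"locus counts TSV needs columns {sorted(required)}")
    return [
        LocusCounts(
            name=str(r["name"]),
            n_polymorphic=int(r["n_polymorphic"]),
            n_divergent=int(r["n_divergent"]),
            length=int(r["length"]) if "length" in df.columns else None,
        )
        for _, r in df.iterrows()
    ]
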