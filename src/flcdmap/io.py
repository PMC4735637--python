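"""Readers and writers for the tabular formats the pipeline speaks.

The central container is :class:`PooledCounts`: per-site base counts for a
set of sequenced lines or pools on one chromosome, in the PoPoolation2
"sync" dialect (tab-separated ``chrom  pos  ref  A:T:C:G:N:del ...`` with
1-based positions).  BED output is 0-based half-open; the conversion happens
here and nowhere else.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, SyncParseError

#: column order of a sync count string
SYNC_BASES = ("A", "T", "C", "G", "N", "del")
_BASE_INDEX = {b: i for i, b in enumerate(SYNC_BASES)}


@dataclass
class PooledCounts:
    """Per-site allele read counts for one or more samples on one chromosome.

    Attributes
    ----------
    chrom : str
        Chromosome / scaffold name (one chromosome per object).
    positions : (n,) int array
        1-based site coordinates, strictly increasing.
    ref : (n,) unicode array
        Reference base per site.
    samples : dict[str, (n, 6) int array]
        Base counts per sample in ``A, T, C, G, N, del`` column order.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    samples: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="<U1")
        n = self.positions.size
        if self.ref.size != n:
            raise InputError("positions and ref must have equal length")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise InputError("positions must be strictly increasing")
        for name, arr in self.samples.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.shape != (n, 6):
                raise InputError(
                    f"sample {name!r}: counts must be (n_sites, 6), got {arr.shape}"
                )
            if np.any(arr < 0):
                raise InputError(f"sample {name!r}: negative counts")
            self.samples[name] = arr

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def sample_names(self) -> list[str]:
        return list(self.samples)

    def depth(self, sample: str) -> np.ndarray:
        """Total read count per site (N and del included)."""
        return self.samples[sample].sum(axis=1)

    def base_count(self, sample: str, base) -> np.ndarray:
        """Count of a base per site; `base` may be a scalar or per-site array."""
        arr = self.samples[sample]
        base = np.asarray(base, dtype="<U3")
        if base.ndim == 0:
            return arr[:, _BASE_INDEX[str(base)]]
        idx = np.array([_BASE_INDEX[b] for b in base])
        return arr[np.arange(arr.shape[0]), idx]

    def subset(self, mask: np.ndarray) -> "PooledCounts":
        return PooledCounts(
            chrom=self.chrom,
            positions=self.positions[mask],
            ref=self.ref[mask],
            samples={k: v[mask] for k, v in self.samples.items()},
        )


def write_sync(counts: PooledCounts, path, header_comments: list[str] | None = None):
    """Write counts as a sync file, with sample names in a trailing header line."""
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write("#chrom\tpos\tref\t" + "\t".join(counts.sample_names) + "\n")
        cols = [
            pd.Series(counts.chrom, index=range(counts.n_sites)),
            pd.Series(counts.positions),
            pd.Series(counts.ref),
        ]
        for name in counts.sample_names:
            arr = counts.samples[name]
            strs = pd.DataFrame(arr).astype(str)
            cols.append(strs.apply(":".join, axis=1))
        pd.concat(cols, axis=1).to_csv(fh, sep="\t", header=False, index=False)


def read_sync(path) -> PooledCounts:
    """Parse a PoPoolation2-style sync file into :class:`PooledCounts`.

    Sample names are taken from a final ``#chrom pos ref name...`` comment
    line when present, else ``sample_1`` ...  Malformed lines raise
    :class:`SyncParseError` with their 1-based line number.
    """
    names = None
    data_start = 0
    with open(path) as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
                data_start += 1
            else:
                break
    if header_lines:
        last = header_lines[-1].lstrip("#").strip()
        fields = last.split("\t")
        if len(fields) >= 4 and fields[0] == "chrom":
            names = fields[3:]

    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty sync file", stacklevel=2)
        return PooledCounts(chrom="", positions=np.array([], dtype=np.int64),
                            ref=np.array([], dtype="<U1"), samples={})
    if df.shape[1] < 4:
        raise SyncParseError(
            f"expected >=4 tab-separated columns, found {df.shape[1]}",
            line_number=data_start + 1,
        )
    n_samples = df.shape[1] - 3
    if names is None or len(names) != n_samples:
        names = [f"sample_{i + 1}" for i in range(n_samples)]

    chrom_col = df.iloc[:, 0]
    if chrom_col.nunique() > 1:
        raise SyncParseError("more than one chromosome in file; split by chromosome")
    try:
        positions = df.iloc[:, 1].astype(np.int64).to_numpy()
    except ValueError:
        bad = df.index[pd.to_numeric(df.iloc[:, 1], errors="coerce").isna()][0]
        raise SyncParseError("non-integer position", line_number=_line_no(path, bad))
    ref = df.iloc[:, 2].to_numpy(dtype="<U1")

    samples: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        parts = df.iloc[:, 3 + j].str.split(":", expand=True)
        if parts.shape[1] != 6 or parts.isna().any().any():
            bad = parts.index[parts.isna().any(axis=1)]
            row = int(bad[0]) if len(bad) else 0
            raise SyncParseError(
                f"sample {name!r}: count field is not A:T:C:G:N:del",
                line_number=_line_no(path, row),
            )
        try:
            arr = parts.astype(np.int64).to_numpy()
        except ValueError:
            raise SyncParseError(f"sample {name!r}: non-integer count")
        samples[name] = arr

    return PooledCounts(chrom=str(chrom_col.iloc[0]), positions=positions,
                        ref=ref, samples=samples)


def _line_no(path, data_row: int) -> int:
    """1-based file line number of the data_row-th non-comment line."""
    with open(path) as fh:
        k = -1
        for i, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            k += 1
            if k == data_row:
                return i
    return data_row + 1


# ---------------------------------------------------------------- BED ------

def write_bed(intervals, path, chrom: str = None, header_comments=None):
    """Write intervals as BED (0-based half-open).

    ``intervals`` is an iterable of ``(start, end)`` in 1-based inclusive
    chromosome coordinates (the sync/TSV convention), or of
    ``(chrom, start, end, *rest)`` tuples already carrying a chromosome.
    """
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        for iv in intervals:
            if chrom is not None:
                start, end = iv[0], iv[1]
                rest = iv[2:]
                fh.write("\t".join(map(str, (chrom, int(start) - 1, int(end), *rest))) + "\n")
            else:
                c, start, end = iv[0], iv[1], iv[2]
                fh.write("\t".join(map(str, (c, int(start) - 1, int(end), *iv[3:]))) + "\n")


def read_bed(path):
    """Read a BED file into a list of ``(chrom, start_1based, end_1based)``."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2]), *f[3:]))
    return out


# ------------------------------------------------------------- config ------

def format_header(params: dict) -> list[str]:
    """Render a parameter dict as TSV header comment lines."""
    return [f"{k} = {v}" for k, v in params.items()]


def write_tsv(df: pd.DataFrame, path, params: dict | None = None):
    """Write a DataFrame as TSV with parameter-provenance header comments."""
    buf = _stdio.StringIO()
    for line in format_header(params or {}):
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
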