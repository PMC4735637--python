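import numpy as np
import pytest

from flcdmap.io import PooledCounts

BASE_IDX = {"A": 0, "T": 1, "C": 2, "G": 3}


def make_counts(positions, ref, sample_specs, chrom="X"):
    """Build a PooledCounts from {sample: [(base, count), ...] per site} specs.

    ``sample_specs`` maps sample name to a list (one entry per site) of
    dicts base->count.
    """
    n = len(positions)
    samples = {}
    for name, sites in sample_specs.items():
        arr = np.zeros((n, 6), dtype=np.int64)
        for i, site in enumerate(sites):
            for base, c in site.items():
                arr[i, BASE_IDX[base]] = c
        samples[name] = arr
    return PooledCounts(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(ref, dtype="<U1"),
        samples=samples,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
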