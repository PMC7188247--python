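import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fragmad as fm

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_bins() -> fm.BinSet:
    return fm.make_bins(50, 1_000_000, seed=11)


@pytest.fixture(scope="session")
def neutral_sample(small_bins):
    """Copy-neutral 2M-fragment sample with GC bias, shared across tests.

    Deep enough that the size-selected arm (~20% retention) still has a
    tMAD noise floor well below the 0.015 detection threshold.
    """
    truth = fm.neutral_truth(small_bins, tf=0.0)
    frags = fm.simulate_fragments(
        truth,
        small_bins,
        2_000_000,
        gc_bias=fm.gaussian_gc_bias(20.0),
        seed=11,
    )
    return frags


def uniform_gc_bins(n_bins, seed, lo=0.35, hi=0.6, bin_size=1_000_000):
    """Bins with i.i.d. uniform GC — no spatial GC autocorrelation, so GC
    structure and genomic position are decoupled."""
    rng = np.random.default_rng(seed)
    start = np.arange(n_bins, dtype=np.int64) * bin_size
    return fm.BinSet(
        chrom=np.full(n_bins, "chrS1", dtype=object),
        start=start,
        end=start + bin_size,
        gc=rng.uniform(lo, hi, n_bins),
        usable=np.ones(n_bins, dtype=bool),
    )


def scattered_gain_truth(bins, frac, copy, tf, n_blocks=4):
    """Truth with `frac` of bins gained at `copy`, spread over n_blocks
    segments so the gained bins sample the whole GC range."""
    n = bins.n_bins
    k = max(1, int(round(n * frac / n_blocks)))
    stride = n // n_blocks
    segments = []
    prev = 0
    for b in range(n_blocks):
        lo = b * stride + (stride - k) // 2
        hi = lo + k
        if lo > prev:
            segments.append(((prev, lo), 2))
        segments.append(((lo, hi), copy))
        prev = hi
    if prev < n:
        segments.append(((prev, n), 2))
    return fm.make_truth(bins, segments, tf)
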