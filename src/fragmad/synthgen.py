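"""Synthetic cfDNA data generation.

Everything downstream of sequencing is driven by three objects that this
module can fabricate with known ground truth:

* a genome partition into fixed-size bins with a smooth GC landscape
  (:func:`make_bins`),
* a somatic copy-number truth — segments of integer tumor copy number at a
  given tumor fraction (:func:`make_truth`),
* plasma fragment tables drawn from a tumor/normal fragment-length mixture
  with multiplicative GC bias (:func:`simulate_fragments`), and
* longitudinal cfDNA concentration series on the two blood-sampling
  schedules used in the two-part study design (:func:`simulate_concentrations`).

The tumor fragment-length mode (145 bp) sits below the mononucleosomal
normal mode (167 bp), which is what makes in-silico size selection
informative. Fragment tables carry a hidden ``origin`` column (tumor/normal)
so tests can assert enrichment without the analysis stages ever reading it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "BinSet",
    "SCNATruth",
    "SizeModel",
    "Schedule",
    "PART1_SCHEDULE",
    "PART2_SCHEDULE",
    "DEFAULT_NORMAL_SIZE",
    "DEFAULT_TUMOR_SIZE",
    "gaussian_gc_bias",
    "make_bins",
    "make_truth",
    "neutral_truth",
    "simulate_fragments",
    "simulate_concentrations",
]

NORMAL_COPY = 2.0


@dataclass(frozen=True)
class SizeModel:
    """Discretized-normal fragment-length model for one cfDNA component.

    Lengths are drawn from N(mode, sd), rounded to the nearest integer and
    clipped to >= 1 bp, so the support is the positive integers.
    """

    label: str
    mode: float
    sd: float

    def __post_init__(self) -> None:
        if self.mode <= 0 or self.sd < 0:
            raise ValueError("SizeModel requires mode > 0 and sd >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, max(1, round(self.mode)), dtype=np.int64)
        lengths = np.rint(rng.normal(self.mode, self.sd, size=n)).astype(np.int64)
        return np.clip(lengths, 1, None)

    def interval_mass(self, lower: int, upper: int) -> float:
        """Probability that a sampled length lies in [lower, upper] (inclusive).

        Exact for the discretized model up to the negligible mass clipped
        below 1 bp.
        """
        lo = max(lower, 1)
        return float(
            norm.cdf(upper + 0.5, self.mode, self.sd)
            - norm.cdf(lo - 0.5, self.mode, self.sd)
        )


DEFAULT_NORMAL_SIZE = SizeModel("normal", mode=167.0, sd=20.0)
DEFAULT_TUMOR_SIZE = SizeModel("tumor", mode=145.0, sd=20.0)


@dataclass
class BinSet:
    """Genome partition: contiguous, sorted, non-overlapping fixed bins.

    Coordinates are 0-based half-open (BED convention). ``gc`` is the GC
    fraction of each bin in [0, 1]; ``usable`` flags bins that enter the
    copy-number analysis.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.start)
        for name in ("chrom", "end", "gc", "usable"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"BinSet field {name!r} has inconsistent length")
        if n == 0:
            raise ValueError("BinSet must contain at least one bin")
        if np.any(self.end <= self.start):
            raise ValueError("BinSet requires end > start for every bin")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("GC fractions must lie in [0, 1]")
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            s, e = self.start[sel], self.end[sel]
            if np.any(np.diff(s) <= 0) or np.any(s[1:] != e[:-1]):
                raise ValueError(
                    f"bins on {c} must be sorted, contiguous and non-overlapping"
                )

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def widths(self) -> np.ndarray:
        return self.end - self.start

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "gc": self.gc,
                "usable": self.usable,
            }
        )


def make_bins(
    n_bins: int,
    bin_size: int,
    gc_range: tuple[float, float] = (0.35, 0.55),
    seed: int = 0,
    chrom: str = "chrS1",
) -> BinSet:
    """Build ``n_bins`` contiguous bins on one synthetic chromosome.

    The GC track is a smoothed (autocorrelated) Gaussian field rescaled into
    ``gc_range``, emulating the slowly varying GC landscape of a real
    genome. Deterministic for a fixed seed.
    """
    if n_bins < 1 or bin_size < 1:
        raise ValueError("n_bins and bin_size must be positive")
    lo, hi = float(gc_range[0]), float(gc_range[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("gc_range must satisfy 0 <= low <= high <= 1")

    rng = np.random.default_rng(seed)
    start = np.arange(n_bins, dtype=np.int64) * bin_size
    end = start + bin_size

    white = rng.normal(size=n_bins)
    width = max(1.0, n_bins / 20.0)
    half = int(3 * width)
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / width) ** 2)
    kern /= kern.sum()
    smooth = np.convolve(np.pad(white, half, mode="wrap"), kern, mode="same")[
        half : half + n_bins
    ]
    span = np.ptp(smooth)
    if span < 1e-12 or hi == lo:
        gc = np.full(n_bins, (lo + hi) / 2.0)
    else:
        gc = lo + (smooth - smooth.min()) / span * (hi - lo)

    return BinSet(
        chrom=np.full(n_bins, chrom, dtype=object),
        start=start,
        end=end,
        gc=gc,
        usable=np.ones(n_bins, dtype=bool),
    )


@dataclass
class SCNATruth:
    """Ground-truth copy-number state for a simulated sample.

    ``copy`` holds the tumor copy number per bin (2 = neutral); ``tf`` is
    the tumor fraction of cfDNA molecules. The expected relative abundance
    of molecules mapping to bin i is ``w_i = (1 - tf) * 2 + tf * c_i``.
    """

    copy: np.ndarray
    tf: float
    segments: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def expected_weight(self) -> np.ndarray:
        return (1.0 - self.tf) * NORMAL_COPY + self.tf * self.copy


def make_truth(
    bins: BinSet,
    segments: Sequence[tuple[tuple[int, int], float]],
    tf: float,
) -> SCNATruth:
    """Validate a segment list and assemble an :class:`SCNATruth`.

    ``segments`` is a list of ``((lo, hi), c)`` with half-open bin-index
    ranges that must partition ``[0, n_bins)`` without gaps or overlaps;
    ``c`` is the integer-valued tumor copy number of the segment.
    """
    if not (0.0 <= tf <= 1.0):
        raise ValueError("tumor fraction must lie in [0, 1]")
    n = bins.n_bins
    ordered = sorted(segments, key=lambda s: s[0][0])
    cursor = 0
    copy = np.full(n, NORMAL_COPY)
    out_segments: list[tuple[int, int, float]] = []
    for (lo, hi), c in ordered:
        if c < 0:
            raise ValueError("copy number must be >= 0")
        if lo != cursor:
            kind = "overlap" if lo < cursor else "gap"
            raise ValueError(
                f"segment ranges must partition the bins: {kind} at bin {min(lo, cursor)}"
            )
        if hi <= lo or hi > n:
            raise ValueError(f"invalid segment range [{lo}, {hi}) for {n} bins")
        copy[lo:hi] = float(c)
        out_segments.append((lo, hi, float(c)))
        cursor = hi
    if cursor != n:
        raise ValueError(f"segment ranges must partition the bins: gap at bin {cursor}")
    return SCNATruth(copy=copy, tf=float(tf), segments=out_segments)


def neutral_truth(bins: BinSet, tf: float = 0.0) -> SCNATruth:
    """All-neutral truth (c = 2 everywhere) at tumor fraction ``tf``."""
    return make_truth(bins, [((0, bins.n_bins), NORMAL_COPY)], tf)


def gaussian_gc_bias(k: float = 20.0, center: float = 0.45) -> Callable[[np.ndarray], np.ndarray]:
    """Unimodal multiplicative coverage bias ``exp(-k * (gc - center)^2)``.

    ``k = 0`` disables the bias. The returned factor is strictly positive,
    producing the smooth coverage-on-GC dependence that GC correction is
    meant to remove.
    """
    if k < 0:
        raise ValueError("k must be >= 0")

    def bias(gc: np.ndarray) -> np.ndarray:
        return np.exp(-k * (np.asarray(gc, dtype=float) - center) ** 2)

    return bias


def simulate_fragments(
    truth: SCNATruth,
    bins: BinSet,
    n_fragments: int,
    size_normal: SizeModel = DEFAULT_NORMAL_SIZE,
    size_tumor: SizeModel = DEFAULT_TUMOR_SIZE,
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a plasma fragment table from the copy-number/GC/size model.

    Each fragment falls in bin i with probability proportional to
    ``w_i * g(gc_i)`` over usable bins (multinomial counts), is of tumor
    origin with probability ``tf * c_i / w_i`` within its bin, gets a length
    from its origin's :class:`SizeModel`, and a start uniform in the bin.
    The ``origin`` column is ground truth for tests only — analysis stages
    must never read it.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if len(truth.copy) != bins.n_bins:
        raise ValueError("truth and bins describe different numbers of bins")

    rng = np.random.default_rng(seed)
    w = truth.expected_weight
    g = np.ones(bins.n_bins) if gc_bias is None else np.asarray(gc_bias(bins.gc), dtype=float)
    if np.any(g <= 0):
        raise ValueError("gc_bias must be strictly positive")
    p = w * g * bins.usable
    total = p.sum()
    if total <= 0:
        raise ValueError("no usable bins with positive weight")
    p = p / total

    counts = rng.multinomial(n_fragments, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_tumor = np.where(w > 0, truth.tf * truth.copy / np.where(w > 0, w, 1.0), 0.0)
    tumor_counts = rng.binomial(counts, p_tumor)

    bin_idx = np.repeat(np.arange(bins.n_bins), counts)
    # first `tumor_counts[i]` fragments of each bin are tumor-origin
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    within = np.arange(n_fragments) - np.repeat(offsets, counts)
    is_tumor = within < np.repeat(tumor_counts, counts)

    widths = bins.widths
    start = bins.start[bin_idx] + rng.integers(0, widths[bin_idx])
    lengths = np.empty(n_fragments, dtype=np.int64)
    n_t = int(is_tumor.sum())
    lengths[is_tumor] = size_tumor.sample(rng, n_t)
    lengths[~is_tumor] = size_normal.sample(rng, n_fragments - n_t)

    chrom_cats, chrom_codes = np.unique(bins.chrom.astype(str)), None
    if len(chrom_cats) == 1:
        chrom = pd.Categorical.from_codes(
            np.zeros(n_fragments, dtype=np.int8), categories=list(chrom_cats)
        )
    else:
        lookup = {c: i for i, c in enumerate(chrom_cats)}
        bin_codes = np.array([lookup[str(c)] for c in bins.chrom], dtype=np.int16)
        chrom = pd.Categorical.from_codes(
            bin_codes[bin_idx], categories=list(chrom_cats)
        )
    frags = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + lengths,
            "origin": pd.Categorical.from_codes(
                is_tumor.astype(np.int8), categories=["normal", "tumor"]
            ),
        }
    )
    frags.attrs["n_fragments"] = n_fragments
    return frags


@dataclass(frozen=True)
class Schedule:
    """Ordered, unique blood-sampling timepoint labels."""

    name: str
    timepoints: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("schedule timepoints must be unique")
        if not self.timepoints:
            raise ValueError("schedule must contain at least one timepoint")


#: Part 1: baseline test/retest, then 30/60/120 min after the first
#: chemotherapy infusion and after the first radiotherapy fraction.
PART1_SCHEDULE = Schedule(
    "part1",
    (
        "baseline_test",
        "baseline_retest",
        "chemo_30min",
        "chemo_60min",
        "chemo_120min",
        "rt_30min",
        "rt_60min",
        "rt_120min",
    ),
)

#: Part 2: baseline, post-first-chemo-cycle (PET/CT planning), then after
#: radiotherapy fractions 1, 11, 22 and 33.
PART2_SCHEDULE = Schedule(
    "part2",
    ("baseline", "post_chemo_pet", "rt_fx1", "rt_fx11", "rt_fx22", "rt_fx33"),
)


def simulate_concentrations(
    schedule: Schedule,
    patients: Sequence[tuple[str, float]],
    sd_meas: float = 1.0,
    trend: Mapping[str, float] | Callable[[str], float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a longitudinal cfDNA concentration table (ng/ml plasma).

    ``patients`` is a sequence of (histology, baseline mean ng/ml). Each
    measurement is ``max(0, baseline + trend(timepoint) + noise)`` with
    mean-zero Gaussian noise of SD ``sd_meas``. The default ``sd_meas=1.0``
    puts 1.96*SD near the 2 ng/ml scale of real assay repeatability.
    """
    if sd_meas < 0:
        raise ValueError("sd_meas must be >= 0")

    def offset(label: str) -> float:
        if trend is None:
            return 0.0
        if callable(trend):
            return float(trend(label))
        return float(trend.get(label, 0.0))

    rng = np.random.default_rng(seed)
    rows = []
    for i, (histology, baseline) in enumerate(patients, start=1):
        pid = f"p{i:02d}"
        for label in schedule.timepoints:
            noise = rng.normal(0.0, sd_meas) if sd_meas > 0 else 0.0
            value = max(0.0, float(baseline) + offset(label) + noise)
            rows.append((pid, histology, label, value))
    return pd.DataFrame(rows, columns=["patient", "histology", "timepoint", "ng_per_ml"])
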