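"""Bin-count copy-number profiling from fragment tables.

The shallow-WGS read-depth route to somatic copy-number alterations:
fragments are counted into fixed genome bins by midpoint, counts are
GC-corrected with a robust local regression of count on GC fraction, the
corrected counts become log2 ratios against the profile median
(copy-number neutrality), and gained/lost regions are called as maximal
runs of bins beyond symmetric log2 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .synthgen import BinSet

__all__ = [
    "BinCounts",
    "CopyNumberProfile",
    "SCNACall",
    "count_fragments",
    "gc_correct",
    "to_log2_profile",
    "call_scnas",
]


@dataclass
class BinCounts:
    """Raw and (optionally) GC-corrected fragment counts per bin."""

    raw: np.ndarray
    usable: np.ndarray
    corrected: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if np.any(self.raw < 0):
            raise ValueError("counts must be non-negative")
        if len(self.usable) != len(self.raw):
            raise ValueError("usable mask length mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.raw)


@dataclass
class CopyNumberProfile:
    """Per-bin log2 ratios relative to copy-number neutrality.

    ``log2`` is NaN on masked bins (unusable or zero count). By
    construction the median of ``2**log2`` over usable bins is 1.
    """

    log2: np.ndarray
    usable: np.ndarray
    median_count: float

    @property
    def values(self) -> np.ndarray:
        """Log2 ratios of the usable bins only."""
        return self.log2[self.usable]


@dataclass(frozen=True)
class SCNACall:
    """One called copy-number segment: half-open bin-index range."""

    start_bin: int
    end_bin: int
    direction: str  # "gain" | "loss"
    mean_log2: float

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


def count_fragments(fragments: pd.DataFrame, bins: BinSet) -> BinCounts:
    """Assign each fragment to the bin containing its midpoint.

    The midpoint is ``floor((start + end) / 2)`` — unambiguous and
    length-unbiased for fragments straddling a bin boundary. Fragments whose
    midpoint falls outside every bin are dropped and counted in
    ``n_dropped``. Fragments on a chromosome absent from ``bins`` are an
    error (mixed coordinate namespaces).
    """
    n = bins.n_bins
    raw = np.zeros(n, dtype=np.int64)
    dropped = 0
    if len(fragments) == 0:
        return BinCounts(raw=raw, usable=bins.usable.copy(), n_dropped=0)

    codes, uniques = pd.factorize(fragments["chrom"])
    frag_chroms = [str(u) for u in uniques]
    bin_chroms = {str(c) for c in np.unique(bins.chrom)}
    unknown = set(frag_chroms) - bin_chroms
    if unknown:
        name = sorted(unknown)[0]
        row = int(np.argmax(codes == frag_chroms.index(name)))
        raise ValueError(
            f"fragment record {row} is on chromosome {name!r}, "
            f"which is not in the bin set"
        )

    mid = (np.asarray(fragments["start"], dtype=np.int64) + np.asarray(fragments["end"], dtype=np.int64)) // 2
    bin_chrom_arr = np.asarray([str(c) for c in bins.chrom])
    for ci, c in enumerate(frag_chroms):
        bsel = bin_chrom_arr == c
        fsel = codes == ci
        if not fsel.any():
            continue
        starts = bins.start[bsel]
        ends = bins.end[bsel]
        global_idx = np.flatnonzero(bsel)
        m = mid[fsel]
        pos = np.searchsorted(starts, m, side="right") - 1
        inside = (pos >= 0) & (m < ends[np.clip(pos, 0, len(ends) - 1)])
        dropped += int((~inside).sum())
        raw += np.bincount(global_idx[pos[inside]], minlength=n)
    return BinCounts(raw=raw, usable=bins.usable.copy(), n_dropped=dropped)


def gc_correct(
    counts: BinCounts,
    bins: BinSet,
    frac: float = 0.5,
    min_bins: int = 20,
) -> BinCounts:
    """Divide out a smooth local-regression fit of raw count on GC fraction.

    ``corrected_i = raw_i / f(gc_i) * median(f)`` where ``f`` is a robust
    LOWESS fit over usable nonzero bins (smoothing span ``frac``), so the
    overall count median is preserved. The fit is two-pass: bins whose
    residual log-ratio deviates from the genome median by more than four
    MADs — copy-number-altered regions, which would otherwise drag the
    local fit wherever they dominate a GC neighborhood — are excluded and
    the bias curve is refit on the remaining (copy-neutral-looking) bins.
    All bins are still corrected. Bins where the fitted value collapses
    (f < 1e-6 * median f) are masked rather than divided. Refuses to fit on
    fewer than ``min_bins`` usable nonzero bins: with so little support the
    smooth fit is unidentifiable and no-correction mode should be used
    instead (pass the raw counts straight to :func:`to_log2_profile`).
    """
    fit_mask = counts.usable & (counts.raw > 0)
    n_fit = int(fit_mask.sum())
    if n_fit < min_bins:
        raise ValueError(
            f"GC correction needs at least {min_bins} usable nonzero bins "
            f"(got {n_fit}); rerun in no-correction mode"
        )
    gc = np.asarray(bins.gc, dtype=float)
    y = counts.raw.astype(float)

    if np.ptp(gc[fit_mask]) < 1e-12 or np.ptp(y[fit_mask]) < 1e-12:
        # degenerate covariate or flat counts: f is constant, corrected = raw
        f_all = np.full(counts.n_bins, float(np.median(y[fit_mask])))
    else:
        x_fit, y_fit = gc[fit_mask], y[fit_mask]
        fitted = lowess(y_fit, x_fit, frac=frac, it=3, return_sorted=False)
        # second pass: drop globally aberrant bins (likely SCNAs) from the
        # bias fit so a contiguous gained/lost segment cannot bend f where
        # its GC values cluster
        log_ratio = np.log2(y_fit / np.maximum(fitted, 1e-300))
        med_lr = np.median(log_ratio)
        mad_lr = np.median(np.abs(log_ratio - med_lr))
        keep = (
            np.abs(log_ratio - med_lr) <= 4.0 * mad_lr
            if mad_lr > 0
            else np.ones(n_fit, dtype=bool)
        )
        if min_bins <= keep.sum() < n_fit:
            fitted = lowess(
                y_fit[keep], x_fit[keep], frac=frac, it=3, return_sorted=False
            )
            x_fit, y_fit = x_fit[keep], y_fit[keep]
        order = np.argsort(x_fit, kind="stable")
        f_all = np.interp(gc, x_fit[order], fitted[order])

    med_f = float(np.median(f_all[fit_mask]))
    usable = counts.usable.copy()
    bad = f_all < 1e-6 * med_f
    usable &= ~bad
    corrected = np.zeros(counts.n_bins, dtype=float)
    ok = usable & ~bad
    corrected[ok] = y[ok] / f_all[ok] * med_f
    return BinCounts(
        raw=counts.raw, usable=usable, corrected=corrected, n_dropped=counts.n_dropped
    )


def to_log2_profile(counts: BinCounts) -> CopyNumberProfile:
    """Log2 ratio of each bin's corrected count over the profile median.

    Zero-count and unusable bins are masked (NaN). Falls back to raw counts
    if no GC-corrected counts are attached (no-correction mode).
    """
    values = counts.corrected if counts.corrected is not None else counts.raw.astype(float)
    sel = counts.usable & (values > 0)
    if not sel.any():
        raise ValueError("cannot build a log2 profile from an all-zero count vector")
    m = float(np.median(values[sel]))
    log2 = np.full(counts.n_bins, np.nan)
    log2[sel] = np.log2(values[sel] / m)
    return CopyNumberProfile(log2=log2, usable=sel, median_count=m)


def call_scnas(
    profile: CopyNumberProfile,
    gain_thresh: float = 0.15,
    loss_thresh: float = -0.15,
    min_bins: int = 10,
) -> list[SCNACall]:
    """Call gained/lost regions as maximal runs of thresholded bins.

    A gain is a maximal run of >= ``min_bins`` consecutive usable bins with
    log2 ratio >= ``gain_thresh``; a loss analogously with <= ``loss_thresh``.
    Unusable bins break runs. Calls are returned in coordinate order. This
    deliberately stays at run-length calling — bin-level increased/decreased
    classification — rather than a segmentation algorithm.
    """
    if not (gain_thresh > 0 > loss_thresh):
        raise ValueError("need gain_thresh > 0 > loss_thresh")
    if min_bins < 1:
        raise ValueError("min_bins must be >= 1")

    r = profile.log2
    state = np.zeros(profile.log2.shape[0], dtype=np.int8)
    state[profile.usable & (r >= gain_thresh)] = 1
    state[profile.usable & (r <= loss_thresh)] = -1
    # usable-but-neutral bins are 0; unusable bins get a sentinel that can
    # never extend a run
    state[~profile.usable] = 2

    calls: list[SCNACall] = []
    i = 0
    n = len(state)
    while i < n:
        s = state[i]
        j = i
        while j < n and state[j] == s:
            j += 1
        if s in (1, -1) and (j - i) >= min_bins:
            seg = r[i:j]
            calls.append(
                SCNACall(
                    start_bin=i,
                    end_bin=j,
                    direction="gain" if s == 1 else "loss",
                    mean_log2=float(np.mean(seg)),
                )
            )
        i = j
    return calls
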