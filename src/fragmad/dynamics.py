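"""Concentration-dynamics statistics for longitudinal cfDNA series.

Operates on long-format tables with columns
``patient, histology, timepoint, ng_per_ml``:

* Bland-Altman agreement of repeated measurements (per-sample difference
  from its within-patient cluster mean; 95% limits = mean +/- 1.96*SD),
* baseline summaries (median/range over patients, per-histology means),
* change from baseline at a named timepoint with per-histology stats,
* an exact two-sided Wilcoxon rank-sum test by enumeration (midranks for
  ties), and Spearman rank correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import norm, rankdata, spearmanr

__all__ = [
    "BlandAltmanResult",
    "BaselineSummary",
    "DeltaSummary",
    "DEFAULT_BASELINE_TIMEPOINTS",
    "PART1_GROUPING",
    "bland_altman",
    "summarize_baseline",
    "change_from_baseline",
    "rank_sum_exact",
    "spearman_rho",
]

#: Timepoint labels treated as baseline measurements. Test/retest baselines
#: are averaged per patient before any summary.
DEFAULT_BASELINE_TIMEPOINTS = ("baseline", "baseline_test", "baseline_retest")

#: Part-1 clustering for the Bland-Altman analysis: each sample is compared
#: with the mean of its own treatment context (baseline pair, post-chemo
#: triplet, post-radiotherapy triplet).
PART1_GROUPING: dict[str, str] = {
    "baseline_test": "baseline",
    "baseline_retest": "baseline",
    "chemo_30min": "chemo",
    "chemo_60min": "chemo",
    "chemo_120min": "chemo",
    "rt_30min": "rt",
    "rt_60min": "rt",
    "rt_120min": "rt",
}

_REQUIRED_COLUMNS = {"patient", "histology", "timepoint", "ng_per_ml"}


def _validate_series(series: pd.DataFrame) -> pd.DataFrame:
    missing = _REQUIRED_COLUMNS - set(series.columns)
    if missing:
        raise ValueError(f"concentration series lacks columns: {sorted(missing)}")
    if len(series) == 0:
        raise ValueError("concentration series is empty")
    if (series["ng_per_ml"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    return series


@dataclass(frozen=True)
class BlandAltmanResult:
    """Differences from cluster means with 95% limits of agreement (ng/ml)."""

    differences: np.ndarray
    mean_diff: float
    sd_diff: float
    lower: float
    upper: float
    n: int


@dataclass(frozen=True)
class BaselineSummary:
    """Baseline cfDNA summary over patients (ng/ml plasma)."""

    median: float
    minimum: float
    maximum: float
    n: int
    per_patient: dict[str, float]
    group_means: dict[str, float]
    group_n: dict[str, int]


@dataclass(frozen=True)
class DeltaSummary:
    """Per-patient change from baseline at one timepoint (ng/ml)."""

    timepoint: str
    deltas: dict[str, float]
    by_histology: dict[str, dict[str, float]]
    excluded: list[str]
    n_included: int
    n_eligible: int


def bland_altman(
    series: pd.DataFrame, grouping: Mapping[str, str] | None = None
) -> BlandAltmanResult:
    """Bland-Altman agreement over repeated within-patient measurements.

    ``grouping`` maps timepoint labels to cluster names; measurements of one
    patient in one cluster are compared with their own cluster mean. Limits
    of agreement are ``mean_diff +/- 1.96 * SD`` with the sample SD (n-1
    denominator). Every (patient, cluster) needs >= 2 measurements.
    """
    _validate_series(series)
    grouping = dict(grouping) if grouping is not None else dict(PART1_GROUPING)
    sub = series[series["timepoint"].isin(grouping)].copy()
    if len(sub) == 0:
        raise ValueError("no measurements fall in the requested clusters")
    sub["cluster"] = sub["timepoint"].map(grouping)

    diffs: list[float] = []
    for (patient, cluster), grp in sub.groupby(["patient", "cluster"], sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"cluster {cluster!r} of patient {patient!r} has a single "
                f"measurement; Bland-Altman needs >= 2 per cluster"
            )
        v = grp["ng_per_ml"].to_numpy(dtype=float)
        diffs.extend(v - v.mean())
    d = np.asarray(diffs)
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    half = 1.96 * sd
    return BlandAltmanResult(
        differences=d,
        mean_diff=mean_diff,
        sd_diff=sd,
        lower=mean_diff - half,
        upper=mean_diff + half,
        n=len(d),
    )


def _baseline_per_patient(
    series: pd.DataFrame, baseline_timepoints: Sequence[str]
) -> pd.DataFrame:
    base = series[series["timepoint"].isin(baseline_timepoints)]
    if len(base) == 0:
        raise ValueError("no baseline measurements in the series")
    per = (
        base.groupby("patient", sort=True)
        .agg(value=("ng_per_ml", "mean"), histology=("histology", "first"))
        .reset_index()
    )
    return per


def summarize_baseline(
    series: pd.DataFrame,
    baseline_timepoints: Sequence[str] = DEFAULT_BASELINE_TIMEPOINTS,
    patients: Sequence[str] | None = None,
) -> BaselineSummary:
    """Median and range of per-patient baseline cfDNA, plus histology means.

    Test/retest baseline records are averaged per patient first. If
    ``patients`` is given, the summary is restricted to that declared
    subset (for instance, the part-2 cohort).
    """
    _validate_series(series)
    per = _baseline_per_patient(series, baseline_timepoints)
    if patients is not None:
        per = per[per["patient"].isin(set(patients))]
        if len(per) == 0:
            raise ValueError("none of the requested patients has a baseline record")
    values = per["value"].to_numpy(dtype=float)
    group_means = {
        h: float(g["value"].mean()) for h, g in per.groupby("histology", sort=True)
    }
    group_n = {h: int(len(g)) for h, g in per.groupby("histology", sort=True)}
    return BaselineSummary(
        median=float(np.median(values)),
        minimum=float(values.min()),
        maximum=float(values.max()),
        n=len(values),
        per_patient=dict(zip(per["patient"], per["value"].astype(float))),
        group_means=group_means,
        group_n=group_n,
    )


def change_from_baseline(
    series: pd.DataFrame,
    timepoint: str,
    baseline_timepoints: Sequence[str] = DEFAULT_BASELINE_TIMEPOINTS,
) -> DeltaSummary:
    """Per-patient delta = value(timepoint) - value(baseline).

    Patients lacking the target timepoint are excluded (and listed, never
    imputed); a patient who has the timepoint but no baseline is an error.
    Per-histology mean and [min, max] are reported over included patients.
    """
    _validate_series(series)
    per_base = _baseline_per_patient(series, baseline_timepoints).set_index("patient")
    at_tp = series[series["timepoint"] == timepoint]
    eligible = sorted(series["patient"].unique())
    included: dict[str, float] = {}
    hist: dict[str, str] = {}
    for patient, grp in at_tp.groupby("patient", sort=True):
        if patient not in per_base.index:
            raise ValueError(f"patient {patient!r} has no baseline measurement")
        delta = float(grp["ng_per_ml"].mean()) - float(per_base.loc[patient, "value"])
        included[patient] = delta
        hist[patient] = str(grp["histology"].iloc[0])
    excluded = [p for p in eligible if p not in included]

    by_histology: dict[str, dict[str, float]] = {}
    for h in sorted(set(hist.values())):
        vals = np.array([d for p, d in included.items() if hist[p] == h])
        by_histology[h] = {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": int(len(vals)),
        }
    return DeltaSummary(
        timepoint=timepoint,
        deltas=included,
        by_histology=by_histology,
        excluded=excluded,
        n_included=len(included),
        n_eligible=len(eligible),
    )


def rank_sum_exact(
    a: Sequence[float], b: Sequence[float], max_exact: int = 12
) -> float:
    """Two-sided Wilcoxon rank-sum p-value, exact for small groups.

    Pooled values get midranks (ties allowed). For group sizes up to
    ``max_exact`` the p-value is exact: the proportion of all
    ``C(|a|+|b|, |a|)`` label assignments whose rank-sum deviates from the
    null mean by at least the observed deviation. Beyond that, a normal
    approximation with tie-corrected variance is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n = len(a), len(pooled)
    obs = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0

    if max(len(a), len(b)) <= max_exact:
        scaled = np.rint(2 * ranks).astype(np.int64)
        total = int(scaled.sum())
        ways = np.zeros((n_a + 1, total + 1), dtype=float)
        ways[0, 0] = 1.0
        for v in scaled:
            for k in range(n_a - 1, -1, -1):
                ways[k + 1, v:] += ways[k, : total + 1 - v]
        sums = np.arange(total + 1) / 2.0
        dev = np.abs(sums - mu)
        obs_dev = abs(obs - mu)
        count = ways[n_a, dev >= obs_dev - 1e-9].sum()
        return float(count / comb(n, n_a, exact=True))

    # tie-corrected normal approximation
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    n_b = len(b)
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (obs - mu) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Undefined (NaN, with a warning) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("Spearman correlation is undefined for a constant vector")
        return float("nan")
    return float(spearmanr(x, y).statistic)
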