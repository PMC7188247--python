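"""Tests for the concentration-dynamics statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import fragmad as fm
from fragmad import datasets
from fragmad.dynamics import PART1_GROUPING
from fragmad.synthgen import PART1_SCHEDULE, PART2_SCHEDULE


def series_of(rows):
    return pd.DataFrame(rows, columns=["patient", "histology", "timepoint", "ng_per_ml"])


def brute_force_ranksum_p(a, b):
    """Independent enumeration oracle: iterate every label assignment
    explicitly with itertools and recompute the rank-sum deviation."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(pooled)
    mu = len(a) * (n + 1) / 2.0
    obs = abs(ranks[: len(a)].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), len(a)):
        total += 1
        hits += abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9
    return hits / total


class TestBlandAltman:
    def test_identical_repeats_give_degenerate_limits(self):
        rows = [
            ("p1", "AC", "baseline_test", 4.0),
            ("p1", "AC", "baseline_retest", 4.0),
            ("p2", "AC", "baseline_test", 7.0),
            ("p2", "AC", "baseline_retest", 7.0),
        ]
        result = fm.bland_altman(series_of(rows), PART1_GROUPING)
        assert result.mean_diff == 0 and result.sd_diff == 0
        assert result.lower == result.upper == 0

    def test_single_pair_hand_computation(self):
        rows = [
            ("p1", "AC", "baseline_test", 4.0),
            ("p1", "AC", "baseline_retest", 6.0),
        ]
        result = fm.bland_altman(series_of(rows), PART1_GROUPING)
        # diffs (-1, +1): mean 0, sample SD sqrt(2), limits +/- 1.96*sqrt(2)
        assert result.mean_diff == pytest.approx(0.0)
        assert result.sd_diff == pytest.approx(math.sqrt(2))
        assert result.upper == pytest.approx(2.77186, abs=1e-4)

    def test_singleton_cluster_is_an_error_naming_it(self):
        rows = [
            ("p1", "AC", "baseline_test", 4.0),
            ("p1", "AC", "baseline_retest", 6.0),
            ("p1", "AC", "chemo_30min", 5.0),
        ]
        with pytest.raises(ValueError, match="chemo"):
            fm.bland_altman(series_of(rows), PART1_GROUPING)

    def test_closed_form_limits_self_consistent(self):
        """Limits recomputed from the reported differences agree to 1e-12."""
        series = fm.simulate_concentrations(
            PART1_SCHEDULE, [("AC", 4.0), ("SCC", 6.0)] * 5, sd_meas=1.0, seed=5
        )
        result = fm.bland_altman(series, PART1_GROUPING)
        d = result.differences
        assert result.mean_diff == pytest.approx(d.mean(), abs=1e-12)
        assert result.sd_diff == pytest.approx(d.std(ddof=1), abs=1e-12)
        assert result.upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)
        assert result.lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)

    def test_part1_limits_match_within_cluster_closed_form(self):
        """Deviations from a size-m cluster mean have SD sigma*sqrt(1-1/m);
        pooling part-1 clusters {2,3,3} gives half-width
        1.96*sigma*sqrt(5/8) at sigma = 1."""
        series = fm.simulate_concentrations(
            PART1_SCHEDULE, [("AC", 10.0)] * 200, sd_meas=1.0, seed=6
        )
        result = fm.bland_altman(series, PART1_GROUPING)
        expected_half = 1.96 * math.sqrt((2 * 0.5 + 3 * (2 / 3) + 3 * (2 / 3)) / 8)
        half = (result.upper - result.lower) / 2
        assert abs(half - expected_half) / expected_half < 0.1


class TestSummarizeBaseline:
    def test_cohort_median_and_range(self):
        summary = fm.summarize_baseline(datasets.baseline_series())
        assert summary.median == pytest.approx(3.86, abs=0.00501)
        assert summary.minimum == pytest.approx(1.47)
        assert summary.maximum == pytest.approx(17.78)
        assert summary.n == 10

    def test_part2_histology_means(self):
        summary = fm.summarize_baseline(
            datasets.baseline_series(), patients=datasets.PART2_PATIENTS
        )
        assert summary.group_means["AC"] == pytest.approx(2.97, abs=0.00501)
        assert summary.group_means["SCC"] == pytest.approx(5.86, abs=0.00501)
        assert summary.group_n == {"AC": 3, "SCC": 3}

    def test_test_retest_baselines_averaged_first(self):
        rows = [
            ("p1", "AC", "baseline_test", 3.0),
            ("p1", "AC", "baseline_retest", 5.0),
            ("p2", "SCC", "baseline", 8.0),
        ]
        summary = fm.summarize_baseline(series_of(rows))
        assert summary.per_patient["p1"] == pytest.approx(4.0)
        assert summary.median == pytest.approx(6.0)

    def test_single_patient_degenerate_summary(self):
        summary = fm.summarize_baseline(series_of([("p1", "AC", "baseline", 2.5)]))
        assert summary.median == summary.minimum == summary.maximum == 2.5

    def test_invariant_to_record_order(self):
        base = datasets.baseline_series()
        shuffled = base.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = fm.summarize_baseline(base)
        b = fm.summarize_baseline(shuffled)
        assert (a.median, a.minimum, a.maximum, a.group_means) == (
            b.median,
            b.minimum,
            b.maximum,
            b.group_means,
        )

    def test_empty_series_is_an_error(self):
        with pytest.raises(ValueError):
            fm.summarize_baseline(series_of([]))


class TestChangeFromBaseline:
    def test_constant_series_has_zero_deltas(self):
        series = fm.simulate_concentrations(
            PART2_SCHEDULE, [("AC", 3.0), ("SCC", 5.0)], sd_meas=0.0, seed=0
        )
        result = fm.change_from_baseline(series, "rt_fx22")
        assert all(d == pytest.approx(0.0) for d in result.deltas.values())

    def test_histology_mean_and_range_of_constructed_deltas(self):
        rows = []
        for pid, delta in [("p1", -2.2), ("p2", 1.27), ("p3", 3.0)]:
            rows.append((pid, "AC", "baseline", 5.0))
            rows.append((pid, "AC", "rt_fx22", 5.0 + delta))
        result = fm.change_from_baseline(series_of(rows), "rt_fx22")
        ac = result.by_histology["AC"]
        assert ac["mean"] == pytest.approx(0.69)
        assert ac["min"] == pytest.approx(-2.2)
        assert ac["max"] == pytest.approx(3.0)

    def test_patient_missing_timepoint_excluded_and_reported(self):
        rows = [
            ("p1", "AC", "baseline", 3.0),
            ("p1", "AC", "rt_fx33", 4.0),
            ("p2", "AC", "baseline", 3.0),
            ("p2", "AC", "rt_fx33", 2.0),
            ("p3", "SCC", "baseline", 3.0),  # missed the rt_fx33 draw
        ]
        result = fm.change_from_baseline(series_of(rows), "rt_fx33")
        assert result.excluded == ["p3"]
        assert result.n_included == 2 and result.n_eligible == 3

    def test_patient_missing_baseline_is_an_error(self):
        rows = [("p1", "AC", "rt_fx22", 4.0)]
        with pytest.raises(ValueError, match="baseline"):
            fm.change_from_baseline(series_of(rows), "rt_fx22")

    def test_zero_trend_deltas_center_on_zero(self):
        """Across seeds, mean delta under a flat trend is within 3 SE of 0."""
        deltas = []
        for seed in range(30):
            series = fm.simulate_concentrations(
                PART2_SCHEDULE, [("AC", 5.0)] * 4, sd_meas=1.0, seed=seed
            )
            result = fm.change_from_baseline(series, "rt_fx22")
            deltas.extend(result.deltas.values())
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / math.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se


class TestRankSumExact:
    def test_single_identical_observations_give_p_one(self):
        assert fm.rank_sum_exact([1.0], [1.0]) == pytest.approx(1.0)

    def test_fully_separated_three_vs_three(self):
        # only the two extreme assignments deviate as far: p = 2/20
        assert fm.rank_sum_exact([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_p_lies_on_enumeration_support(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b = rng.normal(size=3), rng.normal(size=3)
            p = fm.rank_sum_exact(a, b)
            assert (20 * p) == pytest.approx(round(20 * p), abs=1e-9)

    def test_agrees_with_brute_force_enumeration(self):
        """Oracle equivalence on random instances for all sizes <= 5,
        with and without ties."""
        rng = np.random.default_rng(8)
        for na in range(1, 6):
            for nb in range(1, 6):
                for rep in range(4):
                    if rep % 2:
                        a = rng.integers(0, 4, na).astype(float)  # ties likely
                        b = rng.integers(0, 4, nb).astype(float)
                    else:
                        a, b = rng.normal(size=na), rng.normal(size=nb)
                    assert fm.rank_sum_exact(a, b) == pytest.approx(
                        brute_force_ranksum_p(a, b)
                    )

    def test_matches_scipy_exact_mannwhitney_without_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a, b = rng.normal(size=5), rng.normal(size=6)
            ours = fm.rank_sum_exact(a, b)
            scipy_p = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(scipy_p)

    def test_large_groups_fall_back_to_normal_approximation(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=30), rng.normal(size=30)
        p = fm.rank_sum_exact(a, b)
        assert 0 < p <= 1

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            fm.rank_sum_exact([], [1.0])


class TestSpearman:
    def test_monotone_vectors_have_unit_correlation(self):
        x = [1, 2, 3, 4, 5]
        assert fm.spearman_rho(x, [10, 20, 30, 40, 50]) == pytest.approx(1.0)
        assert fm.spearman_rho(x, [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        assert fm.spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_reported_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            rho = fm.spearman_rho([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fm.spearman_rho([1, 2, 3], [1, 2])
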