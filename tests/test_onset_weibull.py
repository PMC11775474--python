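"""Time-to-onset computation, quartiles, Weibull MLE and hazard profiling."""

import math

import numpy as np
import pytest
from scipy import stats

from faerspv.curation import AEReport
from faerspv.faers_io import PartialDate
from faerspv.onset_weibull import (
    OnsetSample,
    TherapyRecord,
    WeibullFit,
    WeibullTTOModel,
    classify_profile,
    compute_tto,
    fit_weibull,
    median_iqr,
    round_half_up,
)

D = PartialDate


def _demo(pid, event):
    return AEReport(primaryid=pid, caseid=pid, fda_dt=D(2023, 1, 1), event_dt=event)


class TestComputeTto:
    def test_simple_date_arithmetic(self):
        sample = compute_tto(
            [TherapyRecord("1", "1", D(2020, 1, 1))],
            [_demo("1", D(2020, 1, 11))],
            {"1"},
        )
        assert list(sample.values) == [10.0]

    def test_event_before_or_at_start_excluded(self):
        sample = compute_tto(
            [TherapyRecord("1", "1", D(2020, 1, 11)),
             TherapyRecord("2", "1", D(2020, 1, 1))],
            [_demo("1", D(2020, 1, 1)), _demo("2", D(2020, 1, 1))],
            {"1", "2"},
        )
        assert sample.n_usable == 0
        assert sample.n_excluded["nonpositive"] == 2

    def test_missing_start_excluded_and_counted(self):
        sample = compute_tto([], [_demo("1", D(2020, 2, 1))], {"1"})
        assert sample.n_usable == 0 and sample.n_excluded["missing_start_dt"] == 1

    def test_earliest_suspect_start_is_used(self):
        sample = compute_tto(
            [TherapyRecord("1", "1", D(2020, 1, 10)),
             TherapyRecord("1", "2", D(2020, 1, 1))],
            [_demo("1", D(2020, 1, 21))],
            {"1"},
        )
        assert list(sample.values) == [20.0]

    def test_suspect_seq_filter_ignores_concomitant_rows(self):
        sample = compute_tto(
            [TherapyRecord("1", "1", D(2020, 1, 10)),
             TherapyRecord("1", "2", D(2020, 1, 1))],   # concomitant, earlier
            [_demo("1", D(2020, 1, 21))],
            {"1"},
            suspect_seqs={("1", "1")},
        )
        assert list(sample.values) == [11.0]

    def test_month_precision_imputes_day_one_year_precision_excluded(self):
        sample = compute_tto(
            [TherapyRecord("1", "1", D(2020, 1)),   # -> 2020-01-01
             TherapyRecord("2", "1", D(2020))],     # year only: unusable
            [_demo("1", D(2020, 3)), _demo("2", D(2020, 3, 1))],
            {"1", "2"},
        )
        assert list(sample.values) == [60.0]
        assert sample.n_excluded["missing_start_dt"] == 1


class TestMedianIqr:
    def test_single_point(self):
        s = median_iqr([10])
        assert (s.median, s.q25, s.q75) == (10, 10, 10)

    def test_odd_length_exact(self):
        s = median_iqr([1, 2, 3, 4, 5])
        assert (s.median, s.q25, s.q75) == (3, 2, 4)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            median_iqr([])

    def test_quartiles_match_closed_form_on_large_weibull_sample(self):
        alpha, beta = 120.0, 0.7
        rng = np.random.default_rng(5)
        x = alpha * rng.weibull(beta, size=10_000)
        x = x[x > 0]
        s = median_iqr(x)
        for q, value in ((0.25, s.q25), (0.5, s.median), (0.75, s.q75)):
            expected = alpha * (-math.log(1 - q)) ** (1 / beta)
            assert value == pytest.approx(expected, rel=0.05)


def test_round_half_up_is_decimal_not_bankers():
    assert round_half_up(2.5) == 3.0
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(46.45, 1) == 46.5


class TestWeibullFit:
    def test_recovers_parameters_and_matches_scipy_mle(self):
        rng = np.random.default_rng(42)
        alpha, beta = 191.02, 0.49
        x = alpha * rng.weibull(beta, size=20_000)
        res = WeibullTTOModel(x).fit()
        assert res.beta == pytest.approx(beta, abs=0.01)
        assert res.alpha == pytest.approx(alpha, rel=0.05)
        # independent oracle: scipy's Weibull MLE with fixed location 0
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        assert res.beta == pytest.approx(c, rel=1e-4)
        assert res.alpha == pytest.approx(scale, rel=1e-4)

    def test_exponential_data_is_weibull_shape_one_random_failure(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(scale=50.0, size=4000)
        res = WeibullTTOModel(x[x > 0]).fit()
        assert res.beta == pytest.approx(1.0, abs=0.05)
        assert res.beta_ci[0] < 1.0 < res.beta_ci[1]
        assert res.profile == "random failure"

    def test_fitted_median_matches_sample_median_at_large_n(self):
        rng = np.random.default_rng(2)
        x = 80.0 * rng.weibull(1.4, size=15_000)
        res = WeibullTTOModel(x).fit()
        assert res.median() == pytest.approx(float(np.median(x)), rel=0.03)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = 30.0 * rng.weibull(0.8, size=2000)
        r1 = WeibullTTOModel(x).fit()
        r2 = WeibullTTOModel(7.0 * x).fit()
        assert r2.alpha == pytest.approx(7.0 * r1.alpha, rel=1e-6)
        assert r2.beta == pytest.approx(r1.beta, rel=1e-6)

    def test_sample_size_floor_enforced(self):
        with pytest.raises(ValueError, match="at least"):
            fit_weibull([1.0, 2.0, 3.0])

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            WeibullTTOModel(np.concatenate([np.ones(40), [0.0]]))

    def test_wald_ci_covers_truth_in_at_least_ninety_percent_of_runs(self):
        """95% beta CI coverage across 100 simulated datasets at n=2000."""
        alpha0, beta0 = 100.0, 0.6
        rng = np.random.default_rng(123)
        covered = 0
        for _ in range(100):
            x = alpha0 * rng.weibull(beta0, size=2000)
            lo, hi = WeibullTTOModel(x).fit().beta_ci
            covered += lo <= beta0 <= hi
        assert covered >= 90


class TestClassifyProfile:
    @pytest.mark.parametrize(
        "beta,ci,expected",
        [
            (0.49, (0.48, 0.495), "early failure"),
            (1.0, (0.9, 1.1), "random failure"),
            (1.6, (1.4, 1.8), "wear-out failure"),
            (0.98, (0.95, 1.0), "random failure"),  # boundary: CI touching 1
        ],
    )
    def test_rules(self, beta, ci, expected):
        fit = WeibullFit(100.0, beta, (90.0, 110.0), ci, expected)
        assert classify_profile(fit) == expected

    def test_rules_partition_all_valid_cis(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            lo = float(rng.uniform(0.1, 2.0))
            hi = lo * float(rng.uniform(1.0, 1.5))
            labels = [
                classify_profile(WeibullFit(1.0, (lo + hi) / 2, (1.0, 1.0), (lo, hi), "x"))
            ]
            assert len(labels) == 1 and labels[0] in (
                "early failure", "random failure", "wear-out failure"
            )


def test_results_summary_prints_estimates():
    rng = np.random.default_rng(4)
    res = WeibullTTOModel(50.0 * rng.weibull(0.7, size=500)).fit()
    text = res.summary()
    assert "shape beta" in text and "failure profile" in text


def test_onset_sample_rejects_nonpositive_values():
    with pytest.raises(ValueError):
        OnsetSample(np.array([3.0, 0.0]), 2)
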