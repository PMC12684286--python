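"""Time-to-onset extraction, descriptives, Weibull MLE, and bootstrap."""

import math

import numpy as np
import pytest
from scipy import stats

from srsignal.dates import PartialDate
from srsignal.model import CaseRecord, DrugEntry, EventEntry, Role
from srsignal.tto import (
    bootstrap_weibull,
    classify_failure,
    collect_tto,
    tto_descriptives,
    weibull_mle,
)


def _case(case_id, start, onset, pt="10008629"):
    return CaseRecord(
        case_id=case_id,
        drugs=[
            DrugEntry(
                raw_name="PEMAFIBRATE",
                canonical_drug="pemafibrate",
                role=Role.PRIMARY_SUSPECT,
                therapy_start=start,
            )
        ],
        events=[EventEntry(pt_code=pt, onset=onset)],
    )


class TestCollect:
    def test_same_day_onset_counts_one_day(self):
        d = PartialDate(2022, 3, 1)
        recs, _ = collect_tto([_case("A", d, d)], "pemafibrate", {"10008629"})
        assert len(recs) == 1 and recs[0].days == 1

    def test_incomplete_dates_excluded_by_reason(self):
        cases = [
            _case("A", PartialDate(2022, 3), PartialDate(2022, 5, 1)),
            _case("B", PartialDate(2022, 3, 1), PartialDate(2022, 5)),
        ]
        recs, excluded = collect_tto(cases, "pemafibrate", {"10008629"})
        assert recs == []
        assert excluded["incomplete_start"] == 1
        assert excluded["incomplete_onset"] == 1

    def test_negative_interval_excluded(self):
        recs, excluded = collect_tto(
            [_case("A", PartialDate(2022, 3, 10), PartialDate(2022, 3, 1))],
            "pemafibrate",
            {"10008629"},
        )
        assert recs == [] and excluded["negative_interval"] == 1

    def test_days_arithmetic_and_plus_one(self):
        recs, _ = collect_tto(
            [_case("A", PartialDate(2022, 1, 1), PartialDate(2022, 1, 31))],
            "pemafibrate",
            {"10008629"},
        )
        assert recs[0].days == 31

    def test_multiple_events_each_contribute(self):
        case = _case("A", PartialDate(2022, 1, 1), PartialDate(2022, 2, 1))
        case.events.append(
            EventEntry(pt_code="10008612", onset=PartialDate(2022, 3, 1))
        )
        recs, _ = collect_tto(case and [case], "pemafibrate", {"10008629", "10008612"})
        assert sorted(r.days for r in recs) == [32, 60]
        recs_e, _ = collect_tto(
            [case], "pemafibrate", {"10008629", "10008612"}, earliest_only=True
        )
        assert [r.days for r in recs_e] == [32]


class TestDescriptives:
    def test_simple_odd_set(self):
        d = tto_descriptives([1, 2, 3, 4, 5])
        assert d == {"median": 3, "q1": 2, "q3": 4, "min": 1, "max": 5}

    def test_singleton(self):
        d = tto_descriptives([7])
        assert all(v == 7 for v in d.values())

    def test_fuzz_against_sort_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            days = rng.integers(1, 1000, size=int(rng.integers(2, 40))).astype(float)
            d = tto_descriptives(list(days))
            assert d["median"] == pytest.approx(np.median(days))
            assert d["q1"] == pytest.approx(np.percentile(days, 25))
            assert d["q3"] == pytest.approx(np.percentile(days, 75))
            assert d["min"] == days.min() and d["max"] == days.max()

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            tto_descriptives([])


class TestWeibullMLE:
    def test_exponential_reduction(self):
        """For beta fixed at 1 the scale MLE is the sample mean; data drawn
        from an exponential should fit a shape near 1."""
        rng = np.random.default_rng(21)
        t = rng.exponential(100.0, size=4000)
        fit = weibull_mle(t)
        assert fit.beta == pytest.approx(1.0, abs=0.05)
        # profile alpha at beta=1 equals the mean exactly
        assert np.power(np.power(t, 1.0).mean(), 1.0) == pytest.approx(t.mean())

    def test_simulation_recovery(self):
        rng = np.random.default_rng(22)
        t = 470.0 * rng.weibull(1.59, size=10_000)
        fit = weibull_mle(t)
        assert fit.alpha == pytest.approx(470.0, rel=0.03)
        assert fit.beta == pytest.approx(1.59, rel=0.03)

    def test_matches_grid_search_oracle(self):
        days = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        alphas = np.linspace(150, 600, 400)
        betas = np.linspace(0.5, 5.0, 400)
        A, B = np.meshgrid(alphas, betas)
        n = days.size
        ll = (
            n * (np.log(B) - B * np.log(A))
            + (B - 1) * np.log(days).sum()
            - ((days[:, None, None] / A) ** B).sum(axis=0)
        )
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        fit = weibull_mle(days)
        assert fit.alpha == pytest.approx(A[i, j], rel=2e-3)
        assert fit.beta == pytest.approx(B[i, j], rel=2e-3)
        assert fit.loglik >= ll.max() - 1e-9

    def test_agrees_with_scipy_fit(self):
        rng = np.random.default_rng(23)
        t = 300.0 * rng.weibull(2.2, size=500)
        fit = weibull_mle(t)
        c, loc, scale = stats.weibull_min.fit(t, floc=0)
        assert fit.beta == pytest.approx(c, rel=1e-4)
        assert fit.alpha == pytest.approx(scale, rel=1e-4)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(24)
        t = 100.0 * rng.weibull(1.4, size=200)
        f1, f2 = weibull_mle(t), weibull_mle(7.5 * t)
        assert f2.beta == pytest.approx(f1.beta, rel=1e-6)
        assert f2.alpha == pytest.approx(7.5 * f1.alpha, rel=1e-6)

    def test_large_sample_median_closed_form(self):
        rng = np.random.default_rng(25)
        alpha, beta = 470.0, 1.59
        t = alpha * rng.weibull(beta, size=100_000)
        assert np.median(t) == pytest.approx(
            alpha * math.log(2) ** (1 / beta), rel=0.02
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            weibull_mle([5.0])
        with pytest.raises(ValueError):
            weibull_mle([5.0, 5.0, 5.0])


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(26)
        t = 470.0 * rng.weibull(1.59, size=17)
        f1 = bootstrap_weibull(t, B=500, seed=9)
        f2 = bootstrap_weibull(t, B=500, seed=9)
        assert f1.beta_ci == f2.beta_ci
        assert f1.alpha_ci == f2.alpha_ci
        assert f1.median_ci == f2.median_ci

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(27)
        t = 470.0 * rng.weibull(1.59, size=17)
        fit = bootstrap_weibull(t, B=2000, seed=3)
        assert fit.beta_ci[0] < fit.beta < fit.beta_ci[1]
        assert 0 < fit.alpha_ci[0] < fit.alpha_ci[1] < math.inf

    def test_classification_attached(self):
        rng = np.random.default_rng(28)
        t = 100.0 * rng.weibull(4.0, size=60)  # strongly increasing hazard
        fit = bootstrap_weibull(t, B=500, seed=1)
        assert fit.classification == "wear_out"


class TestClassify:
    @pytest.mark.parametrize(
        "ci, expected",
        [
            ((1.17, 2.56), "wear_out"),
            ((0.87, 2.94), "random"),
            ((0.3, 0.9), "early_failure"),
            ((1.0, 2.0), "random"),  # boundary: lower must exceed 1 strictly
        ],
    )
    def test_rule(self, ci, expected):
        assert classify_failure(ci) == expected
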