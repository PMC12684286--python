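"""2x2 metrics: ROR, PRR, Fisher exact, BCPNN IC, and the signal rules."""

import math

import numpy as np
import pytest
from scipy import stats

from srsignal.contingency import (
    ContingencyTable,
    MetricResult,
    apply_signal_rules,
    bcpnn_ic,
    build_contingency,
    fisher_exact,
    prr,
    ror,
)
from srsignal.model import DrugEventPair, Role


def _pair(case, drug, event):
    return DrugEventPair(case, drug, event, Role.CONCOMITANT)


def fisher_enumeration(t: ContingencyTable) -> float:
    """Independent oracle: sum hypergeometric point probabilities <= observed."""
    n, k, m = t.n_total, t.n1p, t.np1
    lo, hi = max(0, k + m - n), min(k, m)
    xs = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(xs, n, m, k)
    p_obs = stats.hypergeom.pmf(t.n11, n, m, k)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestBuildContingency:
    def test_brute_force_classification(self):
        pairs = [
            _pair("1", "d", "e"),
            _pair("2", "d", "x"),
            _pair("3", "d", "x"),
            _pair("4", "o", "e"),
            _pair("5", "o", "x"),
            _pair("6", "o", "y"),
        ]
        t = build_contingency(pairs, {"d"}, {"e"})
        assert (t.n11, t.n12, t.n21, t.n22) == (1, 2, 1, 2)
        assert t.n_total == len(pairs)

    def test_empty_drug_set(self):
        t = build_contingency([_pair("1", "d", "e")], set(), {"e"})
        assert t.n11 == 0 and t.n12 == 0 and t.n21 == 1

    def test_all_pairs_qualify(self):
        t = build_contingency([_pair("1", "d", "e")] * 4, {"d"}, {"e"})
        assert (t.n11, t.n12, t.n21, t.n22) == (4, 0, 0, 0)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            build_contingency([], {"d"}, {"e"})

    def test_cell_conservation_fuzz(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pairs = [
                _pair(str(i), str(rng.choice(["d", "o"])), str(rng.choice(["e", "x"])))
                for i in range(int(rng.integers(1, 40)))
            ]
            t = build_contingency(pairs, {"d"}, {"e"})
            assert t.n_total == len(pairs)


class TestROR:
    def test_symmetric_table(self):
        assert ror(ContingencyTable(10, 10, 10, 10)).estimate == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        t = ContingencyTable(5, 95, 10, 890)
        r = ror(t)
        assert r.estimate == pytest.approx(4450 / 950)
        se = math.sqrt(1 / 5 + 1 / 95 + 1 / 10 + 1 / 890)
        z = stats.norm.ppf(0.975)
        assert r.lower == pytest.approx((4450 / 950) * math.exp(-z * se))
        assert r.upper == pytest.approx((4450 / 950) * math.exp(z * se))

    def test_ci_geometric_mean_identity_fuzz(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            cells = rng.integers(1, 500, size=4)
            r = ror(ContingencyTable(*map(int, cells)))
            assert math.sqrt(r.lower * r.upper) == pytest.approx(
                r.estimate, rel=1e-12
            )

    def test_zero_cell_undefined_unless_corrected(self):
        t = ContingencyTable(0, 10, 5, 100)
        r = ror(t)
        assert not r.defined and math.isfinite(r.aux["p_value"])
        rc = ror(t, continuity=True)
        assert rc.defined
        assert rc.estimate == pytest.approx((0.5 * 100.5) / (10.5 * 5.5))


class TestPRR:
    def test_equal_proportions(self):
        r = prr(ContingencyTable(10, 90, 100, 900))
        assert r.estimate == pytest.approx(1.0)
        assert r.aux["chi_square"] == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        r = prr(ContingencyTable(5, 95, 10, 890))
        assert r.estimate == pytest.approx((5 / 100) / (10 / 900))
        assert math.sqrt(r.lower * r.upper) == pytest.approx(r.estimate, rel=1e-12)

    def test_yates_chi_square_matches_scipy(self):
        t = ContingencyTable(12, 88, 40, 860)
        expected = stats.chi2_contingency(
            [[12, 88], [40, 860]], correction=True
        )[0]
        assert prr(t).aux["chi_square"] == pytest.approx(expected)

    def test_ror_dominates_prr_when_positive(self):
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(2000):
            t = ContingencyTable(*(int(x) for x in rng.integers(1, 300, size=4)))
            p, r = prr(t).estimate, ror(t).estimate
            # sign concordance: ROR and PRR sit on the same side of 1
            assert (p - 1) * (r - 1) >= -1e-12
            if p > 1:
                assert r >= p - 1e-12
                checked += 1
        assert checked > 100

    def test_zero_n11_undefined(self):
        r = prr(ContingencyTable(0, 50, 10, 940))
        assert not r.defined


class TestFisher:
    @pytest.mark.parametrize(
        "cells",
        [(1, 9, 11, 3), (0, 5, 5, 0), (2, 2, 2, 2), (5, 95, 10, 890), (3, 0, 7, 11)],
    )
    def test_matches_enumeration_oracle(self, cells):
        t = ContingencyTable(*cells)
        assert fisher_exact(t) == pytest.approx(fisher_enumeration(t), rel=1e-7)

    def test_known_value(self):
        # enumeration for (1,9,11,3): strongly negative association
        t = ContingencyTable(1, 9, 11, 3)
        assert fisher_exact(t) == pytest.approx(0.002759, abs=2e-6)

    def test_mode_table_gives_one(self):
        assert fisher_exact(ContingencyTable(2, 2, 2, 2)) == pytest.approx(1.0)

    def test_symmetry_under_complement(self):
        a = fisher_exact(ContingencyTable(0, 5, 5, 0))
        b = fisher_exact(ContingencyTable(5, 0, 0, 5))
        assert a == pytest.approx(b)


class TestBCPNN:
    def test_zero_when_observed_equals_expected(self):
        # E = 100*110/1100 = 10 = n11
        t = ContingencyTable(10, 90, 100, 900)
        assert t.expected_n11 == pytest.approx(10.0)
        assert bcpnn_ic(t).estimate == pytest.approx(0.0)

    def test_algebraic_identity_fuzz(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            t = ContingencyTable(*(int(x) for x in rng.integers(0, 200, size=4) + 1))
            r = bcpnn_ic(t)
            assert 2 ** r.estimate * (t.expected_n11 + 0.5) == pytest.approx(
                t.n11 + 0.5, rel=1e-12
            )

    def test_interval_matches_monte_carlo_posterior(self):
        t = ContingencyTable(20, 980, 100, 8900)
        r = bcpnn_ic(t)
        rng = np.random.default_rng(5)
        lam = rng.gamma(t.n11 + 0.5, 1.0 / (t.expected_n11 + 0.5), size=1_000_000)
        mc_lo, mc_hi = np.log2(np.quantile(lam, [0.025, 0.975]))
        assert r.lower == pytest.approx(mc_lo, abs=0.01)
        assert r.upper == pytest.approx(mc_hi, abs=0.01)

    def test_degenerate_margins_error(self):
        with pytest.raises(ValueError):
            bcpnn_ic(ContingencyTable(0, 0, 5, 5))

    def test_moment_variant_agrees_on_direction(self):
        t = ContingencyTable(40, 60, 100, 900)
        g = bcpnn_ic(t, variant="gamma")
        m = bcpnn_ic(t, variant="moment")
        assert g.estimate * m.estimate > 0
        assert abs(g.estimate - m.estimate) < 0.5


def _mr(lower, aux=None):
    return MetricResult("x", lower + 1, lower, lower + 2, 0.95, aux or {})


class TestSignalRules:
    def test_minimum_count_gates_ror(self):
        flags = apply_signal_rules(2, ror_result=_mr(5.0))
        assert not flags.ror_signal
        assert apply_signal_rules(3, ror_result=_mr(5.0)).ror_signal

    def test_prr_threshold_is_strict(self):
        at_two = apply_signal_rules(
            10, prr_result=_mr(2.0, {"chi_square": 10.0})
        )
        assert not at_two.prr_signal
        above = apply_signal_rules(
            10, prr_result=_mr(2.0000001, {"chi_square": 10.0})
        )
        assert above.prr_signal

    def test_chi_square_threshold_is_strict(self):
        at_four = apply_signal_rules(10, prr_result=_mr(3.0, {"chi_square": 4.0}))
        assert not at_four.prr_signal

    def test_ic_threshold_is_strict(self):
        assert not apply_signal_rules(10, ic_result=_mr(0.0)).ic_signal
        assert apply_signal_rules(10, ic_result=_mr(0.001)).ic_signal

    def test_ebgm_threshold_is_inclusive(self):
        assert apply_signal_rules(10, ebgm_result=_mr(2.0)).ebgm_signal
        assert not apply_signal_rules(10, ebgm_result=_mr(1.999)).ebgm_signal

    def test_undefined_metrics_never_signal(self):
        undef = MetricResult.undefined("ROR", 0.95)
        flags = apply_signal_rules(10, ror_result=undef)
        assert not flags.ror_signal
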