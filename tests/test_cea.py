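"""Deterministic cost-effectiveness arithmetic."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from varicea import (
    Dominance,
    StrategyOutcome,
    classify_dominance,
    evaluate_scenario,
    icer,
    incremental,
    nmb,
    optimal_at_wtp,
)
from varicea.cea import compare, scenario_outcomes


def _pair(cost_e, qaly_e, cost_h, qaly_h):
    return (
        StrategyOutcome("EVLT", cost_e, qaly_e),
        StrategyOutcome("HLS", cost_h, qaly_h),
    )


class TestIncremental:
    def test_direct_cost_delta(self):
        hls, evlt = StrategyOutcome("HLS", 924.00, 0.0), StrategyOutcome("EVLT", 1390.66, 0.0)
        d_cost, _ = incremental(hls, evlt)
        assert d_cost == pytest.approx(466.66)

    def test_three_month_effect_delta(self):
        evlt, hls = _pair(1390.66, 0.3600, 924.00, 0.3675)
        _, d_eff = incremental(evlt, hls)
        assert d_eff == pytest.approx(0.0075)

    def test_identical_outcomes(self):
        a = StrategyOutcome("EVLT", 100.0, 0.5)
        assert incremental(a, a) == (0.0, 0.0)


class TestIcer:
    def test_tradeoff_ratios_match_published(self):
        assert icer(303.97, 0.025).value == pytest.approx(12158.67, rel=1e-3)
        assert icer(3079.45, 0.0075).value == pytest.approx(410592.89, rel=1e-3)

    def test_zero_effect_is_typed_undefined(self):
        out = icer(466.66, 0.0)
        assert not out.defined and out.reason == "zero effect"

    def test_dominance_signs_are_typed_undefined(self):
        out = icer(466.66, -0.0075)  # costlier and less effective
        assert not out.defined and out.reason == "dominance"
        out = icer(-100.0, 0.01)  # cheaper and more effective
        assert not out.defined and out.reason == "dominance"

    def test_negative_qaly_tradeoff_keeps_ratio(self):
        # both effects negative but delta positive: ratio as printed
        out = icer(438.88, 0.004)
        assert out.value == pytest.approx(109720.0)


class TestClassifyDominance:
    def test_base_case_inputs_dominate_evlt(self, registry):
        for sid in ("base1", "base2", "base3"):
            assert evaluate_scenario(registry, sid).dominance is Dominance.EVLT_DOMINATED

    def test_equal_qaly_higher_cost_dominates_hls(self):
        evlt, hls = _pair(3396.40, 0.735, 4458.00, 0.735)
        assert classify_dominance(evlt, hls) is Dominance.HLS_DOMINATED

    def test_tradeoff(self):
        evlt, hls = _pair(1390.66, 0.1709, 924.00, 0.1605)
        assert classify_dominance(evlt, hls) is Dominance.TRADEOFF

    def test_equal_pair_is_tradeoff(self):
        evlt, hls = _pair(100.0, 0.5, 100.0, 0.5)
        assert classify_dominance(evlt, hls) is Dominance.TRADEOFF

    @given(
        st.floats(1, 10_000), st.floats(-1, 2),
        st.floats(1, 10_000), st.floats(-1, 2),
    )
    def test_antisymmetry(self, ce, qe, ch, qh):
        evlt, hls = _pair(ce, qe, ch, qh)
        swapped_evlt, swapped_hls = _pair(ch, qh, ce, qe)
        label = classify_dominance(evlt, hls)
        swapped = classify_dominance(swapped_evlt, swapped_hls)
        flip = {
            Dominance.EVLT_DOMINATED: Dominance.HLS_DOMINATED,
            Dominance.HLS_DOMINATED: Dominance.EVLT_DOMINATED,
            Dominance.TRADEOFF: Dominance.TRADEOFF,
        }
        assert swapped is flip[label]


class TestNmbAndDecisionRule:
    def test_nmb_at_zero_wtp_is_negative_cost(self):
        out = StrategyOutcome("EVLT", 1363.55, 0.171)
        assert nmb(out, 0.0) == -1363.55

    def test_nmb_direct_evaluation(self):
        out = StrategyOutcome("EVLT", 1363.55, 0.171)
        assert nmb(out, 50_000) == pytest.approx(7186.45)

    def test_equal_outcomes_equal_nmb(self):
        a, b = _pair(500.0, 0.2, 500.0, 0.2)
        for wtp in (0, 10_000, 50_000):
            assert nmb(a, wtp) == nmb(b, wtp)

    def test_decision_switches_at_icer(self):
        # trade-off scenario with ICER ≈ 42201 €/QALY
        evlt, hls = _pair(1363.55, 0.1709, 924.67, 0.1605)
        assert optimal_at_wtp(evlt, hls, 50_000) == "EVLT"
        assert optimal_at_wtp(evlt, hls, 40_000) == "HLS"

    def test_zero_wtp_prefers_cheaper(self):
        evlt, hls = _pair(1363.55, 0.9, 924.67, 0.1)
        assert optimal_at_wtp(evlt, hls, 0.0) == "HLS"

    def test_tie_retains_comparator(self):
        a, b = _pair(500.0, 0.2, 500.0, 0.2)
        assert optimal_at_wtp(a, b, 30_000) == "HLS"

    @given(st.floats(0.001, 0.5), st.floats(1, 5000))
    def test_single_switch_at_icer(self, d_eff, d_cost):
        """For ΔE > 0 trade-offs the decision flips exactly once, at the ICER."""
        evlt, hls = _pair(1000.0 + d_cost, 0.3 + d_eff, 1000.0, 0.3)
        ratio = d_cost / d_eff
        below = optimal_at_wtp(evlt, hls, ratio * 0.99)
        above = optimal_at_wtp(evlt, hls, ratio * 1.01)
        assert below == "HLS" and above == "EVLT"


class TestScenarioEvaluation:
    def test_ordering_is_cheaper_first(self, registry):
        res = evaluate_scenario(registry, "alt7")
        assert res.cheaper.strategy == "EVLT"  # HL/S is costlier under REACTIVE totals
        assert res.delta_cost >= 0

    def test_reported_outcomes_differ_from_inputs_where_published(self, registry):
        raw = scenario_outcomes(registry, "alt10")
        rep = scenario_outcomes(registry, "alt10", use_reported=True)
        assert raw[0].expected_cost == 1390.66
        assert rep[0].expected_cost == 1363.55

    def test_compare_is_consistent_with_parts(self):
        evlt, hls = _pair(1363.55, 0.1709, 924.67, 0.1605)
        res = compare("x", evlt, hls)
        assert res.dominance is Dominance.TRADEOFF
        assert res.icer.value == pytest.approx(438.88 / 0.0104)
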