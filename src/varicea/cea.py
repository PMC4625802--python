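"""Deterministic cost-effectiveness arithmetic.

Given each strategy's expected cost (€) and expected effect (QALYs),
this module computes incremental cost and effect, the incremental
cost-effectiveness ratio (ICER, €/QALY), a weak-dominance label, net
monetary benefit (NMB) and the willingness-to-pay (WTP) decision rule.

Dominance is *weak*: a strategy is dominated when it is no better on
either axis and strictly worse on at least one.  This is what lets
equal-effect, unequal-cost scenarios (the 6-month comparisons, where
both arms reach the same health state) resolve to "dominated" rather
than to a division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import DomainError
from .params import Registry, Strategy
from .utility import qaly


class Dominance(str, Enum):
    EVLT_DOMINATED = "EVLT_dominated"
    HLS_DOMINATED = "HLS_dominated"
    TRADEOFF = "tradeoff"


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected cost and QALYs of one strategy under one scenario."""

    strategy: Strategy
    expected_cost: float
    expected_qaly: float


@dataclass(frozen=True)
class ICERValue:
    """An ICER or a typed reason why none is defined."""

    value: Optional[float]
    reason: Optional[str] = None  # "dominance" | "zero effect" when undefined

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of two strategies for one scenario.

    Deltas follow the table convention comparator-last: the more costly
    strategy minus the cheaper one, so ``delta_cost >= 0``.
    """

    scenario_id: str
    cheaper: StrategyOutcome
    costlier: StrategyOutcome
    delta_cost: float
    delta_effect: float
    icer: ICERValue
    dominance: Dominance

    def ce_ratio(self, outcome: StrategyOutcome) -> Optional[float]:
        """Per-arm cost per QALY (informational, not a decision quantity)."""
        if outcome.expected_qaly == 0:
            return None
        return outcome.expected_cost / outcome.expected_qaly


def incremental(a: StrategyOutcome, b: StrategyOutcome) -> tuple[float, float]:
    """Incremental (cost, effect) of ``b`` relative to ``a``.

    Callers following the reporting convention list the cheaper
    strategy first; :func:`compare` orders automatically.
    """
    return b.expected_cost - a.expected_cost, b.expected_qaly - a.expected_qaly


def icer(delta_cost: float, delta_effect: float) -> ICERValue:
    """ICER of a (ΔC, ΔE) pair, or a typed undefined outcome.

    Undefined with reason ``"zero effect"`` when ΔE = 0, and with
    reason ``"dominance"`` when the signs mean one strategy is simply
    better on both axes (more costly *and* less effective, or cheaper
    *and* more effective) so no trade-off price exists.
    """
    if delta_effect == 0:
        return ICERValue(None, "zero effect")
    if (delta_cost >= 0 and delta_effect < 0) or (delta_cost <= 0 and delta_effect > 0):
        if delta_cost == 0:
            # equal cost, unequal effect: still dominance, no trade-off
            return ICERValue(None, "dominance")
        return ICERValue(None, "dominance")
    return ICERValue(delta_cost / delta_effect)


def classify_dominance(a: StrategyOutcome, b: StrategyOutcome) -> Dominance:
    """Weak-dominance label for an EVLT/HL-S outcome pair.

    ``a`` and ``b`` may be passed in either order; equal cost *and*
    equal effect is a trade-off (nothing separates the strategies).
    """
    by_name = {o.strategy: o for o in (a, b)}
    if set(by_name) != {"EVLT", "HLS"}:
        raise DomainError("classify_dominance needs one EVLT and one HLS outcome")
    e, h = by_name["EVLT"], by_name["HLS"]

    def _weakly_dominated(x: StrategyOutcome, y: StrategyOutcome) -> bool:
        # x dominated by y: no better on either axis, strictly worse on one
        no_better = x.expected_cost >= y.expected_cost and x.expected_qaly <= y.expected_qaly
        strict = x.expected_cost > y.expected_cost or x.expected_qaly < y.expected_qaly
        return no_better and strict

    if _weakly_dominated(e, h):
        return Dominance.EVLT_DOMINATED
    if _weakly_dominated(h, e):
        return Dominance.HLS_DOMINATED
    return Dominance.TRADEOFF


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay: ``wtp × E − C``."""
    if wtp < 0:
        raise DomainError(f"WTP must be nonnegative, got {wtp}")
    return wtp * outcome.expected_qaly - outcome.expected_cost


def optimal_at_wtp(a: StrategyOutcome, b: StrategyOutcome, wtp: float) -> Strategy:
    """Strategy with the higher NMB at ``wtp``; ties keep the comparator HL/S."""
    nmb_a, nmb_b = nmb(a, wtp), nmb(b, wtp)
    if nmb_a == nmb_b:
        return "HLS"
    return a.strategy if nmb_a > nmb_b else b.strategy


def compare(scenario_id: str, a: StrategyOutcome, b: StrategyOutcome) -> CEResult:
    """Full incremental comparison, ordered cheaper-strategy-first."""
    cheaper, costlier = sorted((a, b), key=lambda o: (o.expected_cost, o.strategy))
    d_cost, d_effect = incremental(cheaper, costlier)
    dom = classify_dominance(a, b)
    ratio = icer(d_cost, d_effect) if dom is Dominance.TRADEOFF else ICERValue(None, "dominance")
    return CEResult(
        scenario_id=scenario_id,
        cheaper=cheaper,
        costlier=costlier,
        delta_cost=d_cost,
        delta_effect=d_effect,
        icer=ratio,
        dominance=dom,
    )


def scenario_outcomes(
    registry: Registry,
    scenario_id: str,
    variant: Optional[str] = None,
    use_reported: bool = False,
) -> tuple[StrategyOutcome, StrategyOutcome]:
    """(EVLT, HLS) expected outcomes for a scenario.

    By default QALYs are recomputed as utility × year-fraction from the
    registry's health-state values (the printed QALY column is rounded
    and occasionally inconsistent) and costs are the scenario's input
    costs.  With ``use_reported=True`` the published per-arm expected
    cost/QALY figures of the incremental tables are used where present.
    """
    spec = registry.scenario(scenario_id)
    outcomes = []
    for strategy in ("EVLT", "HLS"):
        if use_reported and spec.reported and strategy in spec.reported:
            rep = spec.reported[strategy]
            outcomes.append(StrategyOutcome(strategy, rep.cost, rep.qaly))
            continue
        cost = registry.cost_input(scenario_id, strategy)
        util = registry.utility_input(scenario_id, strategy, variant=variant)
        outcomes.append(
            StrategyOutcome(strategy, cost.used_cost, qaly(util.value, util.interval))
        )
    return outcomes[0], outcomes[1]


def evaluate_scenario(
    registry: Registry,
    scenario_id: str,
    variant: Optional[str] = None,
    use_reported: bool = False,
) -> CEResult:
    """Deterministic CEA of one scenario straight from the registry."""
    evlt, hls = scenario_outcomes(registry, scenario_id, variant, use_reported)
    return compare(scenario_id, evlt, hls)
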