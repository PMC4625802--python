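"""Validated model parameters: cost sets, utility sets, scenarios.

The decision model compares two strategies for great-saphenous-vein
varicosis — endovenous laser ablation (EVLT) and high ligation with
stripping (HL/S) — across 25 named scenarios (three base cases and 22
alternatives).  Each scenario pairs one *cost set* (direct
procedure costs, or totals including productivity loss from time to
return to work) with one *utility set* (an imputed HUI2 score or a
VAS-derived pain decrement, held for a stated interval).

Parameters ship as a human-editable YAML document
(``varicea/data/parameters.yaml``); :func:`load_parameters` validates
it into an immutable :class:`Registry`.  Published totals take
precedence over the ``direct + TRW × rate`` reconstruction: rows that
disagree by more than one cent are kept as printed and recorded in
``Registry.warnings``.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigError, DomainError
from .intervals import TimeInterval
from .utility import MappingCoefficients

logger = logging.getLogger(__name__)

Strategy = Literal["EVLT", "HLS"]
STRATEGIES: tuple[Strategy, Strategy] = ("EVLT", "HLS")

#: Tolerance (euros) for the total-cost consistency check.
CENT = 0.01


def total_cost(direct_cost: float, trw_days: float, daily_rate: float) -> float:
    """Total cost of a strategy: direct cost plus productivity loss.

    ``trw_days`` is the time to return to work; ``daily_rate`` the per-day
    productivity value (default €285/day in the shipped document).
    """
    if direct_cost < 0 or trw_days < 0 or daily_rate < 0:
        raise DomainError("total_cost arguments must be nonnegative")
    return direct_cost + trw_days * daily_rate


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class CostInput(_Frozen):
    """One strategy's cost parameters within a cost set."""

    strategy: Strategy
    direct_cost: float
    cost_basis: Literal["direct", "total"]
    trw_days: Optional[float] = None
    total_cost: Optional[float] = None
    source_label: str = ""

    @model_validator(mode="after")
    def _validate(self) -> "CostInput":
        if not (self.direct_cost > 0):
            raise DomainError(f"direct cost must be positive, got {self.direct_cost}")
        if self.trw_days is not None and self.trw_days < 0:
            raise DomainError(f"TRW must be nonnegative, got {self.trw_days}")
        if self.cost_basis == "total" and self.total_cost is None:
            raise DomainError("total-basis cost entry lacks total_cost")
        return self

    @property
    def used_cost(self) -> float:
        """The cost the scenario actually uses (total when basis is total)."""
        return self.total_cost if self.cost_basis == "total" else self.direct_cost

    def reconstructed_total(self, daily_rate: float) -> Optional[float]:
        if self.trw_days is None:
            return None
        return total_cost(self.direct_cost, self.trw_days, daily_rate)


class UtilityInput(_Frozen):
    """One strategy's health-state value at a time point.

    ``hui2`` scores are accepted as printed even above 1 (the imputed
    trial scores exceed the conventional dead–perfect-health anchoring);
    ``sg`` utilities must lie in [0, 1]; ``vas_disutility`` values are
    nonpositive decrements.
    """

    strategy: Strategy
    kind: Literal["hui2", "sg", "vas_disutility"]
    value: float
    interval: TimeInterval
    variant: str = "default"
    printed_qaly: Optional[float] = None

    @model_validator(mode="after")
    def _validate(self) -> "UtilityInput":
        if self.kind == "vas_disutility" and self.value > 0:
            raise DomainError(f"VAS disutility must be ≤ 0, got {self.value}")
        if self.kind == "sg" and not (0.0 <= self.value <= 1.0):
            raise DomainError(f"SG utility must be in [0, 1], got {self.value}")
        return self


class ReportedOutcome(_Frozen):
    """Published per-arm expected cost/QALY for a trade-off scenario."""

    cost: float
    qaly: float


class ScenarioSpec(_Frozen):
    """One scenario: a cost-set/utility-set pairing plus metadata."""

    id: str
    cost_set: str
    utility_set: str
    label: str = ""
    variant_policy: str = "EVLT1"
    reported: Optional[dict[Strategy, ReportedOutcome]] = None


BASE_IDS = ("base1", "base2", "base3")
ALT_IDS = tuple(f"alt{i}" for i in range(4, 26))
SCENARIO_IDS = BASE_IDS + ALT_IDS


class Registry(_Frozen):
    """Immutable, cross-validated parameter registry."""

    daily_productivity_rate: float
    wtp: float
    kovacs_slope_per_mm: float
    sg_exponent: float
    psa_sd_fraction: float
    currency: str = "EUR"
    cost_sets: dict[str, dict[Strategy, CostInput]]
    utility_sets: dict[str, dict[Strategy, dict[str, UtilityInput]]]
    scenarios: dict[str, ScenarioSpec]
    coefficient_sets: dict[str, MappingCoefficients] = {}
    warnings: tuple[str, ...] = ()
    model_config = ConfigDict(frozen=True, extra="forbid", arbitrary_types_allowed=True)

    # -- resolution ---------------------------------------------------

    def scenario(self, scenario_id: str) -> ScenarioSpec:
        try:
            return self.scenarios[scenario_id]
        except KeyError:
            raise ConfigError(f"unknown scenario id {scenario_id!r}") from None

    def cost_input(self, scenario_id: str, strategy: Strategy) -> CostInput:
        spec = self.scenario(scenario_id)
        entry = self.cost_sets[spec.cost_set].get(strategy)
        if entry is None:
            raise ConfigError(f"scenario {scenario_id!r}: no cost entry for {strategy}")
        return entry

    def utility_input(
        self, scenario_id: str, strategy: Strategy, variant: Optional[str] = None
    ) -> UtilityInput:
        spec = self.scenario(scenario_id)
        variants = self.utility_sets[spec.utility_set].get(strategy)
        if not variants:
            raise ConfigError(f"scenario {scenario_id!r}: no utility entry for {strategy}")
        if variant is None:
            variant = spec.variant_policy
        if variant in variants:
            return variants[variant]
        if len(variants) == 1:
            return next(iter(variants.values()))
        raise ConfigError(
            f"scenario {scenario_id!r}: variant {variant!r} not among {sorted(variants)}"
        )

    # -- export -------------------------------------------------------

    def audit_frame(self) -> pd.DataFrame:
        """Flat per-scenario/per-arm view of the registry, for CSV audit."""
        rows = []
        for sid, spec in self.scenarios.items():
            for strategy in STRATEGIES:
                cost = self.cost_input(sid, strategy)
                for variant, util in sorted(
                    self.utility_sets[spec.utility_set].get(strategy, {}).items()
                ):
                    rows.append(
                        {
                            "scenario": sid,
                            "strategy": strategy,
                            "variant": variant,
                            "cost_set": spec.cost_set,
                            "cost_basis": cost.cost_basis,
                            "direct_cost": cost.direct_cost,
                            "trw_days": cost.trw_days,
                            "cost_used": cost.used_cost,
                            "utility_set": spec.utility_set,
                            "utility_kind": util.kind,
                            "utility_value": util.value,
                            "interval": str(util.interval),
                            "year_fraction": util.interval.year_fraction,
                            "printed_qaly": util.printed_qaly,
                        }
                    )
        return pd.DataFrame(rows)

    def to_document(self) -> dict:
        """Serialize back to a plain document; parsing it round-trips."""
        doc: dict = {
            "model": {
                "currency": self.currency,
                "daily_productivity_rate": self.daily_productivity_rate,
                "wtp": self.wtp,
                "kovacs_slope_per_mm": self.kovacs_slope_per_mm,
                "sg_exponent": self.sg_exponent,
                "psa_sd_fraction": self.psa_sd_fraction,
            },
            "cost_sets": {},
            "utility_sets": {},
            "scenarios": {},
        }
        for name, entries in self.cost_sets.items():
            out: dict = {"basis": entries["EVLT"].cost_basis,
                         "source": entries["EVLT"].source_label}
            for strategy, c in entries.items():
                cell = {"direct_cost": c.direct_cost}
                if c.trw_days is not None:
                    cell["trw_days"] = c.trw_days
                if c.total_cost is not None:
                    cell["total_cost"] = c.total_cost
                out[strategy] = cell
            doc["cost_sets"][name] = out
        for name, entries in self.utility_sets.items():
            any_util = next(iter(next(iter(entries.values())).values()))
            out = {
                "kind": any_util.kind,
                "interval": {"value": any_util.interval.value,
                             "unit": any_util.interval.unit.value},
            }
            for strategy, variants in entries.items():
                if set(variants) == {"default"}:
                    u = variants["default"]
                    out[strategy] = {"value": u.value, "printed_qaly": u.printed_qaly}
                else:
                    out[strategy] = {
                        v: {"value": u.value, "printed_qaly": u.printed_qaly}
                        for v, u in variants.items()
                    }
            doc["utility_sets"][name] = out
        for sid, spec in self.scenarios.items():
            cell = {"costs": spec.cost_set, "utilities": spec.utility_set,
                    "label": spec.label}
            if spec.reported:
                cell["reported"] = {
                    s: {"cost": r.cost, "qaly": r.qaly} for s, r in spec.reported.items()
                }
            doc["scenarios"][sid] = cell
        if self.coefficient_sets:
            doc["sf36_coefficient_sets"] = {
                name: {"label": c.label, "intercept": c.intercept, "slopes": dict(c.slopes)}
                for name, c in self.coefficient_sets.items()
            }
        return doc


# ---------------------------------------------------------------------
# loading

def _parse_cost_set(name: str, raw: dict) -> dict[Strategy, CostInput]:
    basis = raw.get("basis")
    source = raw.get("source", "")
    entries: dict[Strategy, CostInput] = {}
    for strategy in STRATEGIES:
        if strategy not in raw:
            continue
        cell = dict(raw[strategy])
        entries[strategy] = CostInput(
            strategy=strategy, cost_basis=basis, source_label=source, **cell
        )
    if not entries:
        raise ConfigError(f"cost set {name!r} has no strategy entries")
    return entries


def _parse_utility_set(name: str, raw: dict) -> dict[Strategy, dict[str, UtilityInput]]:
    kind = raw.get("kind")
    interval = TimeInterval(**raw["interval"])
    entries: dict[Strategy, dict[str, UtilityInput]] = {}
    for strategy in STRATEGIES:
        if strategy not in raw:
            continue
        cell = raw[strategy]
        if "value" in cell:  # single (unnamed) variant
            variants = {"default": cell}
        else:
            variants = cell
        entries[strategy] = {
            variant: UtilityInput(
                strategy=strategy, kind=kind, interval=interval, variant=variant, **v
            )
            for variant, v in variants.items()
        }
    if not entries:
        raise ConfigError(f"utility set {name!r} has no strategy entries")
    return entries


def load_parameters(document: dict | str | Path) -> Registry:
    """Validate a parameter document into an immutable :class:`Registry`.

    ``document`` may be a parsed mapping, a YAML string, or a path to a
    YAML file.  Cross-references are checked (every scenario must
    resolve to a cost and a utility entry for both strategies) and the
    total-cost consistency rule is applied; no partial registry is ever
    returned.
    """
    if isinstance(document, Path):
        document = yaml.safe_load(document.read_text())
    elif isinstance(document, str):
        document = yaml.safe_load(document)
    if not isinstance(document, dict) or not document:
        raise ConfigError("empty or non-mapping parameter document")

    try:
        model = document.get("model", {})
        cost_sets = {
            name: _parse_cost_set(name, raw)
            for name, raw in document.get("cost_sets", {}).items()
        }
        utility_sets = {
            name: _parse_utility_set(name, raw)
            for name, raw in document.get("utility_sets", {}).items()
        }
        scenarios: dict[str, ScenarioSpec] = {}
        for sid, raw in document.get("scenarios", {}).items():
            reported = None
            if "reported" in raw:
                reported = {
                    s: ReportedOutcome(**vals) for s, vals in raw["reported"].items()
                }
            scenarios[sid] = ScenarioSpec(
                id=sid,
                cost_set=raw["costs"],
                utility_set=raw["utilities"],
                label=raw.get("label", ""),
                variant_policy=raw.get("variant_policy", "EVLT1"),
                reported=reported,
            )
        coefficient_sets = {
            name: MappingCoefficients(
                intercept=raw["intercept"], slopes=dict(raw["slopes"]),
                label=raw.get("label", name),
            )
            for name, raw in document.get("sf36_coefficient_sets", {}).items()
        }
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    except KeyError as exc:
        raise ConfigError(f"missing required key: {exc}") from exc

    if not scenarios:
        raise ConfigError("parameter document defines no scenarios")

    # cross-reference validation
    for sid, spec in scenarios.items():
        if spec.cost_set not in cost_sets:
            raise ConfigError(f"scenario {sid!r} references unknown cost set {spec.cost_set!r}")
        if spec.utility_set not in utility_sets:
            raise ConfigError(
                f"scenario {sid!r} references unknown utility set {spec.utility_set!r}"
            )
        for strategy in STRATEGIES:
            if strategy not in cost_sets[spec.cost_set]:
                raise ConfigError(f"scenario {sid!r}: missing {strategy} cost entry")
            if strategy not in utility_sets[spec.utility_set]:
                raise ConfigError(f"scenario {sid!r}: missing {strategy} utility entry")

    # total-cost consistency: printed totals are authoritative
    rate = float(model.get("daily_productivity_rate", 285.0))
    warnings: list[str] = []
    for name, entries in cost_sets.items():
        for strategy, c in entries.items():
            if c.total_cost is None or c.trw_days is None:
                continue
            rebuilt = c.reconstructed_total(rate)
            if abs(rebuilt - c.total_cost) > CENT:
                msg = (
                    f"cost set {name!r} [{strategy}]: printed total {c.total_cost:.2f} "
                    f"differs from direct + TRW×rate = {rebuilt:.2f}; keeping printed value"
                )
                warnings.append(msg)
                logger.warning(msg)

    return Registry(
        currency=model.get("currency", "EUR"),
        daily_productivity_rate=rate,
        wtp=float(model.get("wtp", 50000.0)),
        kovacs_slope_per_mm=float(model.get("kovacs_slope_per_mm", 0.035)),
        sg_exponent=float(model.get("sg_exponent", 2.27)),
        psa_sd_fraction=float(model.get("psa_sd_fraction", 0.5)),
        cost_sets=cost_sets,
        utility_sets=utility_sets,
        scenarios=scenarios,
        coefficient_sets=coefficient_sets,
        warnings=tuple(warnings),
    )


#: (utility_set, strategy, variant) cells whose published QALY cannot be
#: reproduced as value × year-fraction under any of the model's time
#: conventions.  The published figures are carried as inputs; these
#: cells are flagged by :func:`qaly_consistency_frame` and excluded
#: from reproduction checks.  The day-7 Kalteis EVLT cell is consistent
#: with a score of −0.66 rather than the printed −0.606; the alternative
#: 6-month pair repeats the base-case QALY 0.735 for scores 1.467/1.473.
CATALOGUED_QALY_INCONSISTENCIES = (
    ("kalteis_day7", "EVLT", "default"),
    ("rasmussen_6mo_alt", "EVLT", "default"),
    ("rasmussen_6mo_alt", "HLS", "default"),
)

#: Reproduction tolerance for printed QALY cells.
QALY_TOLERANCE = 2e-4


def _printed_decimals(x: float) -> int:
    text = repr(float(x))
    return len(text.split(".")[1]) if "." in text else 0


def qaly_consistency_frame(registry: Registry) -> pd.DataFrame:
    """Recompute every printed QALY cell and flag inconsistencies.

    A cell is consistent when the recomputed value, rounded to the
    printed precision, agrees with the printed figure within
    :data:`QALY_TOLERANCE` (printed cells are themselves rounded).
    """
    rows = []
    for set_name, entries in registry.utility_sets.items():
        for strategy, variants in entries.items():
            for variant, util in variants.items():
                if util.printed_qaly is None:
                    continue
                recomputed = util.value * util.interval.year_fraction
                dp = _printed_decimals(util.printed_qaly)
                deviation = abs(round(recomputed, dp) - util.printed_qaly)
                rows.append(
                    {
                        "utility_set": set_name,
                        "strategy": strategy,
                        "variant": variant,
                        "value": util.value,
                        "year_fraction": util.interval.year_fraction,
                        "recomputed_qaly": recomputed,
                        "printed_qaly": util.printed_qaly,
                        "deviation": deviation,
                        # tiny epsilon absorbs binary-float noise at the band edge
                        "consistent": deviation <= QALY_TOLERANCE + 1e-12,
                        "catalogued": (set_name, strategy, variant)
                        in CATALOGUED_QALY_INCONSISTENCIES,
                    }
                )
    return pd.DataFrame(rows)


def default_parameters_path() -> Path:
    """Path of the parameter document shipped with the package."""
    return Path(resources.files("varicea").joinpath("data/parameters.yaml"))


def default_registry() -> Registry:
    """Load the shipped default parameter document (25 scenarios)."""
    return load_parameters(default_parameters_path())


def config_schema() -> dict:
    """JSON Schema of the validated registry (published in-repo)."""
    return Registry.model_json_schema()
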