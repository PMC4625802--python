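"""Whole-analysis orchestration: run scenarios, build report tables.

``run_all`` evaluates every requested scenario deterministically (and,
when iterations are requested, probabilistically), partitions the
scenarios into the three dominance membership lists, and
``build_icer_table`` lays the trade-off scenarios out as an incremental
cost-effectiveness table (cheaper strategy first, per-arm cost/QALY and
cost-per-QALY ratio, incremental columns on the comparator row).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cea import CEResult, Dominance, evaluate_scenario, optimal_at_wtp, scenario_outcomes
from .errors import ConfigError
from .params import Registry, SCENARIO_IDS
from .psa import PSAResult, run_psa

logger = logging.getLogger(__name__)

#: The 21 alternatives enumerated in the three published dominance
#: tables (alternative 20 runs but is absent from them).
DOMINANCE_TABLE_IDS = tuple(
    f"alt{i}" for i in (4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 21, 22, 23, 24, 25)
)


@dataclass(frozen=True)
class RunManifest:
    """What to run and how."""

    scenario_ids: tuple[str, ...] = SCENARIO_IDS
    wtp: float = 50_000.0
    n_iter: int = 0  # 0 = deterministic only
    seed: int = 0
    out_prefix: Optional[str] = None
    variant: Optional[str] = None
    sd_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.wtp < 0:
            raise ConfigError(f"WTP must be nonnegative, got {self.wtp}")
        if self.n_iter < 0:
            raise ConfigError(f"n_iter must be nonnegative, got {self.n_iter}")


@dataclass(frozen=True)
class RunReport:
    results: dict[str, CEResult]
    psa: dict[str, PSAResult]
    membership: dict[Dominance, tuple[str, ...]]
    wtp: float
    optimal: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {dom.value: len(ids) for dom, ids in self.membership.items()}


def run_all(registry: Registry, manifest: RunManifest) -> RunReport:
    """Run every scenario in the manifest; any failure names the scenario.

    Scenarios run in the manifest's order (the published numbering by
    default); results are deterministic given (manifest, seed).
    """
    unknown = [sid for sid in manifest.scenario_ids if sid not in registry.scenarios]
    if unknown:
        raise ConfigError(f"manifest names unknown scenarios: {unknown}")

    results: dict[str, CEResult] = {}
    psa_results: dict[str, PSAResult] = {}
    optimal: dict[str, str] = {}
    membership: dict[Dominance, list[str]] = {d: [] for d in Dominance}
    for sid in manifest.scenario_ids:
        try:
            res = evaluate_scenario(registry, sid, variant=manifest.variant)
            evlt, hls = scenario_outcomes(registry, sid, variant=manifest.variant)
            optimal[sid] = optimal_at_wtp(evlt, hls, manifest.wtp)
            if manifest.n_iter:
                psa_results[sid] = run_psa(
                    registry, sid, n_iter=manifest.n_iter, wtp=manifest.wtp,
                    seed=manifest.seed, variant=manifest.variant,
                    sd_fraction=manifest.sd_fraction,
                )
        except Exception as exc:
            raise ConfigError(f"scenario {sid!r} failed: {exc}") from exc
        results[sid] = res
        membership[res.dominance].append(sid)
        note = f"ICER {res.icer.value:.2f}" if res.icer.defined else (res.icer.reason or "")
        logger.info("%s: %s %s", sid, res.dominance.value, note)
    return RunReport(
        results=results,
        psa=psa_results,
        membership={d: tuple(ids) for d, ids in membership.items()},
        wtp=manifest.wtp,
        optimal=optimal,
    )


def scenario_frame(report: RunReport) -> pd.DataFrame:
    """One row per scenario: costs, QALYs, deltas, ICER, dominance."""
    rows = []
    for sid, res in report.results.items():
        by_name = {o.strategy: o for o in (res.cheaper, res.costlier)}
        row = {
            "scenario": sid,
            "cost_EVLT": by_name["EVLT"].expected_cost,
            "cost_HLS": by_name["HLS"].expected_cost,
            "qaly_EVLT": by_name["EVLT"].expected_qaly,
            "qaly_HLS": by_name["HLS"].expected_qaly,
            "delta_cost": res.delta_cost,
            "delta_effect": res.delta_effect,
            "icer": res.icer.value,
            "icer_note": res.icer.reason,
            "dominance": res.dominance.value,
            "optimal_at_wtp": report.optimal.get(sid),
        }
        if sid in report.psa:
            row["p_evlt_ce_at_wtp"] = report.psa[sid].certainty_ce
        rows.append(row)
    return pd.DataFrame(rows)


def build_icer_table(
    registry: Registry,
    scenario_ids: Sequence[str],
    use_reported: bool = True,
) -> pd.DataFrame:
    """Incremental cost-effectiveness table for trade-off scenarios.

    Two rows per scenario, cheaper strategy first; the costlier row
    carries the incremental columns.  Dominated scenarios get a
    dominance note instead of an ICER.  With ``use_reported`` the
    published per-arm expected outcomes are used where the registry
    carries them (they differ from the raw inputs for several rows).
    """
    rows = []
    for sid in scenario_ids:
        res = evaluate_scenario(registry, sid, use_reported=use_reported)
        for which, outcome in (("first", res.cheaper), ("second", res.costlier)):
            row = {
                "scenario": sid,
                "strategy": outcome.strategy,
                "cost": outcome.expected_cost,
                "effectiveness_qaly": outcome.expected_qaly,
                "ce_ratio": res.ce_ratio(outcome),
            }
            if which == "second":
                row["incremental_cost"] = res.delta_cost
                row["incremental_effect"] = res.delta_effect
                if res.dominance is Dominance.TRADEOFF and res.icer.defined:
                    row["icer"] = res.icer.value
                    row["note"] = ""
                else:
                    row["icer"] = None
                    row["note"] = (
                        res.dominance.value
                        if res.dominance is not Dominance.TRADEOFF
                        else res.icer.reason
                    )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# writers (byte-stable: fixed column order, fixed float formatting)

def write_reports(
    registry: Registry, report: RunReport, out_prefix: str | Path
) -> list[Path]:
    """Write the scenario table, summary JSON, ICER table and PSA CSVs.

    Returns the paths written.  Output is byte-stable for a fixed
    (manifest, seed).
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    frame = scenario_frame(report)
    path = prefix.with_name(prefix.name + "_scenarios.csv")
    frame.to_csv(path, index=False, float_format="%.6f")
    written.append(path)

    tradeoffs = list(report.membership.get(Dominance.TRADEOFF, ()))
    table = build_icer_table(registry, tradeoffs)
    path = prefix.with_name(prefix.name + "_icer_table.csv")
    table.to_csv(path, index=False, float_format="%.6f")
    written.append(path)

    summary = {
        "wtp": report.wtp,
        "counts": report.counts,
        "membership": {d.value: list(ids) for d, ids in report.membership.items()},
        "optimal_at_wtp": report.optimal,
        "certainty_ce": {sid: r.certainty_ce for sid, r in report.psa.items()},
        "registry_warnings": list(registry.warnings),
    }
    path = prefix.with_name(prefix.name + "_summary.json")
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(path)

    for sid, psa_res in report.psa.items():
        scatter = pd.DataFrame(
            {
                "iter": range(psa_res.n_iter),
                "delta_cost": psa_res.samples[:, 0],
                "delta_effect": psa_res.samples[:, 1],
            }
        )
        path = prefix.with_name(f"{prefix.name}_{sid}_scatter.csv")
        scatter.to_csv(path, index=False, float_format="%.6f")
        written.append(path)
        curve = pd.DataFrame(
            {
                "wtp": psa_res.ceac_wtp,
                "p_evlt": psa_res.ceac_p_evlt,
                "p_hls": 1.0 - psa_res.ceac_p_evlt,
            }
        )
        path = prefix.with_name(f"{prefix.name}_{sid}_ceac.csv")
        curve.to_csv(path, index=False, float_format="%.6f")
        written.append(path)
    return written
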