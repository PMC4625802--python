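"""Probabilistic sensitivity analysis.

Parameter uncertainty is expressed with triangular distributions, the
standard choice when trials report only summary statistics:

* from quartiles — the (min, max) are set by *doubling* the distance
  from the mean to the lower/upper quartile, with the mean as mode;
* from a standard-deviation rule — when only a point estimate exists,
  the SD is assumed to be a fixed fraction of the mean (default 0.5)
  and a symmetric triangular with that SD is built around it
  (half-width = SD × √6, since a symmetric triangular of full width w
  has variance w²/24).

Each Monte Carlo iteration redraws every strategy's cost and
health-state value, reruns the deterministic QALY/incremental
arithmetic, and records the incremental (ΔC, ΔE) pair of EVLT versus
HL/S.  Aggregates are quadrant fractions on the cost-effectiveness
plane (with the north-east quadrant split at the WTP line), the
probability that EVLT is cost-effective at the threshold, and the
cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .cea import scenario_outcomes
from .errors import ConfigError, DomainError
from .params import Registry
from .utility import qaly

Derivation = Literal["from_quartiles", "from_sd_halfmean", "explicit"]


@dataclass(frozen=True)
class DistributionSpec:
    """A triangular distribution (min, mode, max) with its provenance."""

    minimum: float
    mode: float
    maximum: float
    derivation: Derivation = "explicit"
    kind: str = "triangular"

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mode <= self.maximum):
            raise DomainError(
                f"triangular parameters must satisfy min ≤ mode ≤ max, "
                f"got ({self.minimum}, {self.mode}, {self.maximum})"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.minimum == self.maximum

    @property
    def mean(self) -> float:
        return (self.minimum + self.mode + self.maximum) / 3.0

    @property
    def variance(self) -> float:
        a, c, b = self.minimum, self.mode, self.maximum
        return (a * a + b * b + c * c - a * b - a * c - b * c) / 18.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.is_degenerate:
            return np.full(size, self.mode)
        return rng.triangular(self.minimum, self.mode, self.maximum, size=size)


def triangular_from_quartiles(mean: float, q1: float, q3: float) -> DistributionSpec:
    """Triangular spread from reported quartiles: double the IQR arms.

    ``min = mean − 2(mean − q1)``, ``mode = mean``,
    ``max = mean + 2(q3 − mean)``.
    """
    if not (q1 <= mean <= q3):
        raise DomainError(f"need q1 ≤ mean ≤ q3, got ({q1}, {mean}, {q3})")
    if q1 == mean == q3:
        raise DomainError("zero-width quartile spread gives a degenerate distribution")
    return DistributionSpec(
        minimum=mean - 2.0 * (mean - q1),
        mode=mean,
        maximum=mean + 2.0 * (q3 - mean),
        derivation="from_quartiles",
    )


def triangular_from_sd(mean: float, sd_fraction: float = 0.5) -> DistributionSpec:
    """Symmetric triangular around a lone point estimate.

    The SD is taken as ``sd_fraction × |mean|`` (the fallback used when
    a trial reports no spread), giving half-width ``sd × √6``.
    """
    if mean == 0:
        raise DomainError("cannot build a spread around a zero point estimate (no scale)")
    if sd_fraction < 0:
        raise DomainError(f"sd_fraction must be nonnegative, got {sd_fraction}")
    half_width = sd_fraction * abs(mean) * math.sqrt(6.0)
    return DistributionSpec(
        minimum=mean - half_width,
        mode=mean,
        maximum=mean + half_width,
        derivation="from_sd_halfmean",
    )


@dataclass(frozen=True)
class QuadrantFractions:
    """Cost-effectiveness-plane partition (EVLT − HL/S deltas).

    ``nw`` — EVLT more costly, less effective (HL/S dominates);
    ``ne_above``/``ne_below`` — EVLT more costly and more effective,
    split by whether its ICER exceeds the WTP; ``se`` — EVLT cheaper
    and more effective (EVLT dominates); ``sw`` — everything else.
    """

    nw: float
    ne_above: float
    ne_below: float
    se: float
    sw: float

    def as_dict(self) -> dict[str, float]:
        return {
            "nw": self.nw,
            "ne_above_wtp": self.ne_above,
            "ne_below_wtp": self.ne_below,
            "se": self.se,
            "sw": self.sw,
        }

    @property
    def total(self) -> float:
        return self.nw + self.ne_above + self.ne_below + self.se + self.sw


@dataclass(frozen=True)
class PSAResult:
    scenario_id: str
    n_iter: int
    seed: int
    wtp: float
    samples: np.ndarray = field(repr=False)  # shape (n_iter, 2): ΔC, ΔE
    quadrants: QuadrantFractions
    certainty_ce: float  # P(EVLT cost-effective at wtp)
    ceac_wtp: np.ndarray = field(repr=False)
    ceac_p_evlt: np.ndarray = field(repr=False)


def quadrant_fractions(samples: np.ndarray, wtp: float) -> QuadrantFractions:
    """Partition (ΔC, ΔE) samples into plane quadrants.

    Boundary conventions: ΔE = 0 with ΔC > 0 counts as north-west
    (HL/S weakly dominates), as does the origin (comparator retained);
    any other boundary point falls into the south-west remainder.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise DomainError("quadrant_fractions needs a nonempty sample set")
    dc, de = samples[:, 0], samples[:, 1]
    n = len(dc)

    nw = (dc > 0) & (de < 0)
    ne = (dc > 0) & (de > 0)
    se = (dc < 0) & (de > 0)
    # boundary assignments
    nw |= (de == 0) & (dc > 0)
    nw |= (dc == 0) & (de == 0)
    ne_below = ne & (dc <= wtp * de)  # ICER ≤ wtp
    ne_above = ne & ~ (dc <= wtp * de)
    sw = ~(nw | ne | se)
    return QuadrantFractions(
        nw=nw.sum() / n,
        ne_above=ne_above.sum() / n,
        ne_below=ne_below.sum() / n,
        se=se.sum() / n,
        sw=sw.sum() / n,
    )


def ceac(samples: np.ndarray, wtp_grid: Sequence[float]) -> np.ndarray:
    """P(EVLT optimal) at each WTP: fraction with positive incremental NMB.

    A sample's incremental NMB is ``wtp × ΔE − ΔC``; ties (exactly
    zero) retain the comparator HL/S.  P(HL/S) is the complement.
    """
    samples = np.asarray(samples, dtype=float)
    grid = np.asarray(wtp_grid, dtype=float)
    if samples.size == 0:
        raise DomainError("ceac needs a nonempty sample set")
    dc, de = samples[:, 0], samples[:, 1]
    inb = grid[:, None] * de[None, :] - dc[None, :]
    return (inb > 0).mean(axis=1)


DEFAULT_WTP_GRID = np.arange(0.0, 100_001.0, 1000.0)


def scenario_distributions(
    registry: Registry,
    scenario_id: str,
    variant: Optional[str] = None,
    sd_fraction: Optional[float] = None,
    quartiles: Optional[dict[str, tuple[float, float]]] = None,
) -> dict[str, DistributionSpec]:
    """Per-parameter triangular specs for one scenario.

    Keys are ``cost_EVLT``, ``cost_HLS``, ``utility_EVLT``,
    ``utility_HLS``.  ``quartiles`` may supply ``(q1, q3)`` per key to
    use the doubling rule; otherwise the SD-fraction fallback applies.
    ``sd_fraction = 0`` collapses every distribution to a point mass
    (the zero-uncertainty override).
    """
    if sd_fraction is None:
        sd_fraction = registry.psa_sd_fraction
    quartiles = quartiles or {}
    means: dict[str, float] = {}
    for strategy in ("EVLT", "HLS"):
        means[f"cost_{strategy}"] = registry.cost_input(scenario_id, strategy).used_cost
        means[f"utility_{strategy}"] = registry.utility_input(
            scenario_id, strategy, variant=variant
        ).value
    specs: dict[str, DistributionSpec] = {}
    for key, mean in means.items():
        if key in quartiles:
            q1, q3 = quartiles[key]
            specs[key] = triangular_from_quartiles(mean, q1, q3)
        elif sd_fraction == 0:
            specs[key] = DistributionSpec(mean, mean, mean, derivation="explicit")
        else:
            specs[key] = triangular_from_sd(mean, sd_fraction)
    return specs


def run_psa(
    registry: Registry,
    scenario_id: str,
    n_iter: int = 10_000,
    wtp: Optional[float] = None,
    seed: int = 0,
    variant: Optional[str] = None,
    sd_fraction: Optional[float] = None,
    quartiles: Optional[dict[str, tuple[float, float]]] = None,
    wtp_grid: Optional[Sequence[float]] = None,
    n_inner: int = 1,
) -> PSAResult:
    """Monte Carlo recalculation of one scenario's incremental outcome.

    Each of the ``n_iter`` iterations draws both strategies' cost and
    health-state value from their triangular specs, converts utilities
    to QALYs over the scenario's interval, and records the EVLT − HL/S
    deltas.  Deterministic under a fixed seed.

    ``n_inner`` exposes an outer/inner (parameter vs evaluation) split;
    the decision model is deterministic given its parameters, so inner
    replicates are identical and the default of 1 loses nothing.
    """
    if n_iter < 1:
        raise DomainError(f"n_iter must be ≥ 1, got {n_iter}")
    if scenario_id not in registry.scenarios:
        raise ConfigError(f"unknown scenario id {scenario_id!r}")
    if wtp is None:
        wtp = registry.wtp
    grid = np.asarray(DEFAULT_WTP_GRID if wtp_grid is None else wtp_grid, dtype=float)

    spec = registry.scenario(scenario_id)
    interval = registry.utility_input(scenario_id, "EVLT", variant=variant).interval
    dists = scenario_distributions(registry, scenario_id, variant, sd_fraction, quartiles)

    rng = np.random.default_rng(seed)
    draws = {key: d.sample(rng, n_iter) for key, d in dists.items()}
    # n_inner > 1 requests an outer (parameter) / inner (evaluation)
    # split; the model is deterministic given its parameters, so the
    # inner replicates coincide and collapse to a single evaluation.
    del n_inner

    qaly_evlt = qaly(draws["utility_EVLT"], interval)
    qaly_hls = qaly(draws["utility_HLS"], interval)
    delta_cost = draws["cost_EVLT"] - draws["cost_HLS"]
    delta_effect = qaly_evlt - qaly_hls
    samples = np.column_stack([delta_cost, delta_effect])

    quadrants = quadrant_fractions(samples, wtp)
    p_grid = ceac(samples, grid)
    certainty = float(ceac(samples, [wtp])[0])
    assert spec.id == scenario_id
    return PSAResult(
        scenario_id=scenario_id,
        n_iter=n_iter,
        seed=seed,
        wtp=wtp,
        samples=samples,
        quadrants=quadrants,
        certainty_ce=certainty,
        ceac_wtp=grid,
        ceac_p_evlt=p_grid,
    )
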