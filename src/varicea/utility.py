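"""Utility derivation and QALY conversion.

Three pathways turn trial quality-of-life measurements into
health-state values:

1. ``hui2_from_sf36`` — a linear multi-attribute mapping from the eight
   SF-36 domain scores to a Health Utilities Index Mark II (HUI2)
   score.  The regression coefficients are injected, never hard-coded:
   the published mapping literature offers several coefficient sets and
   the scenario registry treats trial-level HUI2 scores as inputs.
2. ``sg_from_vas`` — the classic power transformation from a rescaled
   visual-analogue-scale rating to a standard-gamble utility,
   ``1 − (1 − v)^k`` with ``v = VAS/100``.
3. ``kovacs_disutility`` — a linear pain decrement: each millimetre of
   VAS pain subtracts a fixed utility amount (default 0.035/mm, from a
   published EQ-5D regression in low-back-pain patients, assumed
   transferable).

``qaly`` then weights any health-state value (or decrement) by the
year fraction of the interval it is held for.
"""

from __future__ import annotations

from dataclasses import dataclass

from pydantic import BaseModel, model_validator

from .errors import DomainError
from .intervals import TimeInterval

SF36_DOMAINS = ("PF", "RP", "BP", "GH", "VT", "SF", "RE", "MH")

#: Default exponent of the VAS -> SG power curve (Torrance-style
#: conversion; the conventional population-level estimate).
DEFAULT_SG_EXPONENT = 2.27

#: Default utility decrement per mm of VAS pain.
KOVACS_SLOPE_PER_MM = 0.035


@dataclass(frozen=True)
class SF36Profile:
    """Eight SF-36 domain scores, each on the 0 (worst) – 100 (best) scale.

    Domains: Physical Functioning, Role-Physical, Bodily Pain, General
    Health, Vitality, Social Functioning, Role Emotional, Mental Health.
    """

    PF: float
    RP: float
    BP: float
    GH: float
    VT: float
    SF: float
    RE: float
    MH: float

    def __post_init__(self) -> None:
        for name in SF36_DOMAINS:
            score = getattr(self, name)
            if not (0.0 <= score <= 100.0):
                raise DomainError(f"SF-36 domain {name} = {score} outside [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SF36_DOMAINS}


class MappingCoefficients(BaseModel, frozen=True):
    """Intercept and per-domain slopes of a linear SF-36 -> utility map."""

    intercept: float
    slopes: dict[str, float] = {}
    label: str = "unnamed"

    @model_validator(mode="after")
    def _validate(self) -> "MappingCoefficients":
        unknown = set(self.slopes) - set(SF36_DOMAINS)
        if unknown:
            raise DomainError(f"unknown SF-36 domains in coefficients: {sorted(unknown)}")
        values = [self.intercept, *self.slopes.values()]
        if not all(v == v and abs(v) != float("inf") for v in values):
            raise DomainError(f"non-finite coefficient in set '{self.label}'")
        return self


def hui2_from_sf36(profile: SF36Profile, coeffs: MappingCoefficients) -> float:
    """Impute a HUI2 utility score from an SF-36 profile.

    Returns ``intercept + Σ slope_d × score_d``.  The result is not
    clamped: imputed trial-level scores above 1 occur in the registry
    and are carried as-is.
    """
    return coeffs.intercept + sum(
        slope * getattr(profile, domain) for domain, slope in coeffs.slopes.items()
    )


def sg_from_vas(vas: float, exponent: float = DEFAULT_SG_EXPONENT) -> float:
    """Transform a 0–100 VAS rating into a standard-gamble utility.

    The rating is rescaled to [0, 1] and pushed through the power curve
    ``1 − (1 − v)^exponent``; the result is bounded in [0, 1] and
    monotone nondecreasing in ``vas`` for any positive exponent.
    """
    if not (0.0 <= vas <= 100.0):
        raise DomainError(f"VAS score {vas} outside [0, 100]")
    if not (exponent > 0):
        raise DomainError(f"power-curve exponent must be > 0, got {exponent}")
    v = vas / 100.0
    return 1.0 - (1.0 - v) ** exponent


def kovacs_disutility(vas_mm: float, slope: float = KOVACS_SLOPE_PER_MM) -> float:
    """Utility decrement for a VAS pain rating in mm: ``−slope × vas_mm``.

    The decrement is nonpositive and linear in pain.
    """
    if not (0.0 <= vas_mm <= 100.0):
        raise DomainError(f"VAS pain {vas_mm} mm outside [0, 100]")
    return -slope * vas_mm


def qaly(value: float, interval: TimeInterval) -> float:
    """Quality-adjusted life years accrued holding ``value`` over ``interval``.

    ``value`` may be a utility score or a (negative) decrement; the sign
    is preserved.  A 12-month interval returns the value unchanged.
    """
    return value * interval.year_fraction
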