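"""Time intervals and their year-fraction conventions.

All utilities in the model are converted to QALYs by multiplying a
health-state value by the fraction of a year the state is occupied.
The conventions are:

* months: ``m / 12``
* weeks:  ``w / 52``
* days:   ``d / 364`` (a 52-week, 364-day year, so that 7 days and
  1 week carry identical weight)

The 364-day year is deliberate: day-based decrements in the source
trials (e.g. a −0.28 utility decrement held for 7 days) convert to
QALYs of −0.28 × 7/364 = −0.0053846, matching the published model
cell for cell, which a 365-day year does not.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, model_validator

from .errors import DomainError

DAYS_PER_YEAR = 364.0
WEEKS_PER_YEAR = 52.0
MONTHS_PER_YEAR = 12.0


class TimeUnit(str, Enum):
    days = "days"
    weeks = "weeks"
    months = "months"


_DIVISOR = {
    TimeUnit.days: DAYS_PER_YEAR,
    TimeUnit.weeks: WEEKS_PER_YEAR,
    TimeUnit.months: MONTHS_PER_YEAR,
}


class TimeInterval(BaseModel, frozen=True):
    """A strictly positive duration with an explicit unit.

    The model horizon is at most six months, so every interval used by
    the scenario registry has a year fraction in (0, 1].
    """

    value: float
    unit: TimeUnit

    @model_validator(mode="after")
    def _check_positive(self) -> "TimeInterval":
        if not (self.value > 0):
            raise DomainError(f"interval value must be > 0, got {self.value}")
        return self

    @property
    def year_fraction(self) -> float:
        return self.value / _DIVISOR[self.unit]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        v = self.value
        txt = f"{v:g} {self.unit.value}"
        return txt[:-1] if v == 1 else txt


def days(d: float) -> TimeInterval:
    return TimeInterval(value=d, unit=TimeUnit.days)


def weeks(w: float) -> TimeInterval:
    return TimeInterval(value=w, unit=TimeUnit.weeks)


def months(m: float) -> TimeInterval:
    return TimeInterval(value=m, unit=TimeUnit.months)
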