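"""Lifetime QALY projection with annual discounting.

The model: surgery lifts a patient's utility from its pre-operative
level to the one-year level over the course of the first year, and the
gain then persists unchanged for the rest of the patient's remaining
life expectancy.  The comparator is a hypothetical untreated patient
who stays at the pre-operative utility forever at zero cost, so the
incremental QALY stream is simply the gain itself.  Future QALYs are
discounted at an annual rate ``r`` with end-of-year factors
``(1+r)^-t``; costs all fall in year one and are not discounted.

Two conventions for year one are provided:

* ``linear_ramp`` (default): the utility rises linearly during year
  one, so that year contributes half the gain, undiscounted; full
  gain accrues from year two on, discounted from t=1.
* ``full_gain``: the full gain is counted from year one, with year one
  discounted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .cohort import Cohort
from .errors import CuaError, DomainError
from .lifetable import LifeTable

__all__ = [
    "EconParams",
    "QalyProjection",
    "annuity_factor",
    "lifetime_qaly_gain",
    "remaining_life_expectancy",
    "project_cohort",
]

FirstYearModel = Literal["linear_ramp", "full_gain"]


@dataclass
class EconParams:
    """Economic parameters of the evaluation.

    Attributes
    ----------
    discount_rate
        Annual discount rate applied to future QALYs (baseline 0.03).
    first_year_model
        How the first post-operative year enters the QALY sum; see
        module docstring.
    gdp_per_capita_cny
        Per-capita GDP used for WHO-style willingness-to-pay thresholds
        (default: China 2012, 38,354 CNY).
    exchange_rate_cny_per_usd
        Fixed conversion rate for reporting USD figures (default 6.29,
        the 2012-12-31 rate).
    wtp_threshold_cny_per_qaly
        Willingness-to-pay threshold λ; defaults to 3 × GDP per capita.
    """

    discount_rate: float = 0.03
    first_year_model: FirstYearModel = "linear_ramp"
    gdp_per_capita_cny: float = 38354.0
    exchange_rate_cny_per_usd: float = 6.29
    wtp_threshold_cny_per_qaly: Optional[float] = None

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise DomainError(f"discount_rate must be >= 0, got {self.discount_rate}")
        if self.exchange_rate_cny_per_usd <= 0:
            raise DomainError("exchange_rate_cny_per_usd must be positive")
        if self.first_year_model not in ("linear_ramp", "full_gain"):
            raise DomainError(f"unknown first_year_model {self.first_year_model!r}")
        if self.gdp_per_capita_cny <= 0:
            raise DomainError("gdp_per_capita_cny must be positive")
        if self.wtp_threshold_cny_per_qaly is None:
            self.wtp_threshold_cny_per_qaly = 3.0 * self.gdp_per_capita_cny
        if self.wtp_threshold_cny_per_qaly <= 0:
            raise DomainError("wtp_threshold_cny_per_qaly must be positive")


@dataclass(frozen=True)
class QalyProjection:
    """Discounted incremental QALYs for one patient versus no treatment."""

    patient_id: str
    gain: float
    life_expectancy: float
    discounted_qalys_gained: float


def annuity_factor(n_years, rate):
    """Present value of a unit annual stream over ``n_years`` years.

    Whole years are discounted at end-of-year factors ``(1+rate)^-t``
    for t = 1..floor(n); a fractional final year contributes
    ``frac(n) * (1+rate)^-ceil(n)``.  At rate 0 this is exactly
    ``n_years``.  Accepts scalars or numpy arrays for ``n_years``.
    """
    n = np.asarray(n_years, dtype=float)
    if np.any(n < 0):
        raise DomainError("n_years must be >= 0")
    if rate < 0:
        raise DomainError("rate must be >= 0")
    if rate == 0:
        out = n
    else:
        whole = np.floor(n)
        frac = n - whole
        # v^m = exp(-m log(1+r)); expm1/log1p keep precision at tiny rates
        log_v = -np.log1p(rate)
        # geometric sum v + v^2 + ... + v^whole, in closed form (0 when whole == 0)
        out = -np.expm1(whole * log_v) / rate + frac * np.exp((whole + 1.0) * log_v)
    if np.isscalar(n_years) or np.ndim(n_years) == 0:
        return float(out)
    return out


def lifetime_qaly_gain(gain, life_expectancy, params: EconParams):
    """Discounted incremental QALYs from a sustained utility gain.

    Under ``linear_ramp`` the first year contributes ``gain * 0.5``
    undiscounted and the remaining ``life_expectancy - 1`` years an
    annuity of ``gain``; under ``full_gain`` the whole expectancy is an
    annuity of ``gain`` with year one discounted once.  Accepts scalar
    or array ``gain``/``life_expectancy``.
    """
    L = np.asarray(life_expectancy, dtype=float)
    if np.any(L <= 0):
        raise DomainError("life_expectancy must be positive")
    r = params.discount_rate
    if params.first_year_model == "linear_ramp":
        out = np.asarray(gain) * (0.5 + annuity_factor(np.maximum(L - 1.0, 0.0), r))
    else:
        out = np.asarray(gain) * annuity_factor(L, r)
    if np.ndim(out) == 0:
        return float(out)
    return out


def remaining_life_expectancy(age: float, sex: str, table: LifeTable) -> float:
    """Table lookup with linear interpolation and an old-age clamp."""
    return table.expectancy(age, sex)


def project_cohort(cohort: Cohort, table: LifeTable, params: EconParams) -> list[QalyProjection]:
    """One discounted QALY projection per patient.

    The hypothetical no-treatment control stays at the pre-operative
    utility with zero cost, so each patient's incremental QALYs equal
    the projection of their own utility gain.
    """
    cohort.require_nonempty("project_cohort")
    out: list[QalyProjection] = []
    for rec in cohort:
        try:
            L = remaining_life_expectancy(rec.age, rec.sex, table)
            G = lifetime_qaly_gain(rec.utility_gain, L, params)
        except CuaError as exc:
            raise type(exc)(f"patient {rec.patient_id!r}: {exc}") from exc
        out.append(QalyProjection(rec.patient_id, rec.utility_gain, L, G))
    return out


def projected_gains(projections: list[QalyProjection]) -> np.ndarray:
    """Array of discounted QALY gains, in cohort order."""
    return np.array([p.discounted_qalys_gained for p in projections], dtype=float)
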