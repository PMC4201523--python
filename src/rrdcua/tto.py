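"""Time-trade-off (TTO) utility elicitation.

In a TTO interview the respondent states how many additional years they
expect to live and how many of those years they would give up in exchange
for permanently perfect vision.  The health-state utility is

    u = 1 - years_traded / years_expected

so trading nothing values the current state at 1.0 (perfect health) and
trading everything values it at 0.0 (equivalent to death).  Fractional
years are allowed; the formula is continuous in both arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

__all__ = ["TtoResponse", "tto_utility", "utility_gain"]


@dataclass(frozen=True)
class TtoResponse:
    """One respondent's answer to the time-trade-off question.

    Parameters
    ----------
    years_expected
        Self-perceived remaining life expectancy in years; must be > 0.
    years_traded
        Years the respondent would give up for perfect vision;
        must lie in [0, years_expected].
    """

    years_expected: float
    years_traded: float

    def __post_init__(self) -> None:
        if not self.years_expected > 0:
            raise DomainError(
                f"years_expected must be positive, got {self.years_expected}"
            )
        if not 0 <= self.years_traded <= self.years_expected:
            raise DomainError(
                f"years_traded must lie in [0, {self.years_expected}], "
                f"got {self.years_traded}"
            )


def tto_utility(response: TtoResponse) -> float:
    """Utility value implied by a TTO response: ``1 - traded/expected``.

    Always in [0, 1]; monotone decreasing in ``years_traded`` at fixed
    ``years_expected`` and invariant under rescaling both years by a
    common factor.
    """
    return 1.0 - response.years_traded / response.years_expected


def utility_gain(utility_pre: float, utility_post: float) -> float:
    """Change in utility between two elicitations, ``post - pre``.

    Both utilities must lie in [0, 1].  Negative gains (deterioration)
    are permitted and preserved.
    """
    for name, u in (("utility_pre", utility_pre), ("utility_post", utility_post)):
        if not 0.0 <= u <= 1.0:
            raise DomainError(f"{name} must lie in [0, 1], got {u}")
    return utility_post - utility_pre
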