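"""Sensitivity analyses: discount scenarios, ±10% perturbations,
breakeven limits and subgroup/exclusion reruns.

Cost and QALY multipliers are applied as deterministic transforms of
the baseline bootstrap replicates: scaling every patient cost by m
scales every replicate mean cost by exactly m, so transforming the
replicate vectors is equivalent to re-running the bootstrap on scaled
data with the same seed, and it makes the "+10%" rows exact linear
images of the baseline.  Scenarios that change the discount rate or
drop patients genuinely change the resampling problem and are re-run
through the full pipeline under the same seed policy, so that rows of
the sensitivity table are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .cohort import Cohort
from .econ import BootstrapResult, BootstrapSettings, bootstrap_cua, percentile_interval
from .errors import AnalysisError, DomainError
from .lifetable import LifeTable
from .qaly import EconParams, project_cohort, projected_gains

__all__ = [
    "SensitivityScenario",
    "default_scenarios",
    "run_scenarios",
    "breakeven_limits",
    "apply_filter",
]


@dataclass(frozen=True)
class SensitivityScenario:
    """One row of the sensitivity battery.

    At most one cohort filter (bilateral exclusion, age group or
    surgery type) may be set per scenario; multipliers must be
    positive.  ``discount_rate=None`` keeps the baseline rate.
    """

    label: str
    discount_rate: Optional[float] = None
    cost_multiplier: float = 1.0
    qaly_multiplier: float = 1.0
    exclude_bilateral: bool = False
    age_group: Optional[str] = None       # "70-79" or "80+"
    surgery_type: Optional[str] = None    # "scleral_buckle" or "vitrectomy"

    def __post_init__(self) -> None:
        if self.cost_multiplier <= 0 or self.qaly_multiplier <= 0:
            raise DomainError(f"scenario {self.label!r}: multipliers must be positive")
        n_filters = sum([self.exclude_bilateral,
                         self.age_group is not None,
                         self.surgery_type is not None])
        if n_filters > 1:
            raise DomainError(
                f"scenario {self.label!r}: at most one cohort filter per scenario"
            )

    @property
    def is_pure_rescale(self) -> bool:
        """True when the scenario is a deterministic transform of the baseline."""
        return (self.discount_rate is None and not self.exclude_bilateral
                and self.age_group is None and self.surgery_type is None)


def default_scenarios() -> list[SensitivityScenario]:
    """The standard battery: discount 0%/5%, ±10% perturbations, exclusion."""
    return [
        SensitivityScenario("discount_0pct", discount_rate=0.0),
        SensitivityScenario("discount_5pct", discount_rate=0.05),
        SensitivityScenario("cost_plus_10pct", cost_multiplier=1.10),
        SensitivityScenario("qaly_minus_10pct", qaly_multiplier=0.90),
        SensitivityScenario("cost_plus_10pct_qaly_minus_10pct",
                            cost_multiplier=1.10, qaly_multiplier=0.90),
        SensitivityScenario("exclude_bilateral", exclude_bilateral=True),
    ]


def apply_filter(cohort: Cohort, scenario: SensitivityScenario) -> Cohort:
    """Cohort restricted by the scenario's filter; records are shared, not copied."""
    recs = cohort.records
    if scenario.exclude_bilateral:
        recs = [r for r in recs if not r.bilateral]
    if scenario.age_group is not None:
        recs = [r for r in recs if r.age_group == scenario.age_group]
    if scenario.surgery_type is not None:
        recs = [r for r in recs if r.surgery_type == scenario.surgery_type]
    if not recs:
        raise AnalysisError(f"scenario {scenario.label!r} filter empties the cohort")
    return Cohort(recs, provenance=cohort.provenance, currency=cohort.currency)


def rescale_result(base: BootstrapResult, cost_multiplier: float,
                   qaly_multiplier: float) -> BootstrapResult:
    """Exact linear image of a bootstrap result under cost/QALY multipliers."""
    s = base.settings
    delta_cost = base.delta_cost * cost_multiplier
    delta_qaly = base.delta_qaly * qaly_multiplier
    # multiply then divide so that a lone cost multiplier scales each ICER
    # exactly and a lone QALY multiplier divides it exactly
    return BootstrapResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icers=base.icers * cost_multiplier / qaly_multiplier,
        mean_cost=base.mean_cost * cost_multiplier,
        cost_ci=percentile_interval(delta_cost, s.ci_lower, s.ci_upper),
        mean_qaly=base.mean_qaly * qaly_multiplier,
        qaly_ci=percentile_interval(delta_qaly, s.ci_lower, s.ci_upper),
        mean_icer=base.mean_icer * cost_multiplier / qaly_multiplier,
        icer_of_means=base.icer_of_means * cost_multiplier / qaly_multiplier,
        n_excluded=base.n_excluded,
        settings=s,
    )


@dataclass
class ScenarioResult:
    """Bootstrap output of one scenario plus the cohort size it used."""

    scenario: SensitivityScenario
    result: BootstrapResult
    n_patients: int


def _run_full(cohort: Cohort, table: LifeTable, params: EconParams,
              settings: BootstrapSettings) -> BootstrapResult:
    projections = project_cohort(cohort, table, params)
    return bootstrap_cua(cohort.costs(), projected_gains(projections), settings)


def run_scenarios(cohort: Cohort, table: LifeTable, params: EconParams,
                  scenarios: list[SensitivityScenario],
                  settings: BootstrapSettings,
                  baseline: Optional[BootstrapResult] = None,
                  ) -> dict[str, ScenarioResult]:
    """Run the full pipeline once per scenario.

    Pure cost/QALY rescalings reuse the baseline replicates (exact
    transforms); discount overrides and cohort filters re-project and
    re-bootstrap under the same seed.  ``baseline`` may be supplied to
    avoid recomputing it; it must come from the same cohort, params and
    settings.
    """
    if baseline is None:
        baseline = _run_full(cohort, table, params, settings)
    out: dict[str, ScenarioResult] = {}
    for sc in scenarios:
        if sc.label in out:
            raise AnalysisError(f"duplicate scenario label {sc.label!r}")
        if sc.is_pure_rescale:
            res = rescale_result(baseline, sc.cost_multiplier, sc.qaly_multiplier)
            n = len(cohort)
        else:
            sub = apply_filter(cohort, sc)
            p = params if sc.discount_rate is None else replace(
                params, discount_rate=sc.discount_rate)
            res = _run_full(sub, table, p, settings)
            if sc.cost_multiplier != 1.0 or sc.qaly_multiplier != 1.0:
                res = rescale_result(res, sc.cost_multiplier, sc.qaly_multiplier)
            n = len(sub)
        out[sc.label] = ScenarioResult(sc, res, n)
    return out


def breakeven_limits(mean_icer: float, wtp_threshold: float) -> tuple[float, float]:
    """How far costs may rise, or QALYs fall, before the verdict flips.

    Returns ``(cost_increase_limit, qaly_decrease_limit)`` as
    proportions: multiplying costs by ``1 + cost_increase_limit`` or
    QALYs by ``1 - qaly_decrease_limit`` moves the ICER exactly to the
    willingness-to-pay threshold.  If the ICER already meets or exceeds
    the threshold both limits are 0 (no headroom).
    """
    if mean_icer <= 0 or wtp_threshold <= 0:
        raise DomainError("mean_icer and wtp_threshold must be positive")
    if mean_icer >= wtp_threshold:
        return 0.0, 0.0
    cost_limit = wtp_threshold / mean_icer - 1.0
    qaly_limit = 1.0 - mean_icer / wtp_threshold
    return cost_limit, qaly_limit
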