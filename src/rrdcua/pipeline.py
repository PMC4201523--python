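"""End-to-end cost-utility analysis of a cohort.

``run_cua`` ties the pieces together: project each patient's utility
gain over remaining life expectancy, bootstrap the incremental means
and ICER for the whole cohort and for the standard subgroups (age
70-79 / 80+, scleral buckling / vitrectomy), trace the CEAC, read off
willingness-to-pay thresholds at 50/70/90% acceptability, attach the
WHO-convention verdict, and run the sensitivity battery on the
age-based groups.  The output is a plain nested dict of JSON-friendly
types so a run can be serialised, audited (replicate vectors included)
and re-rendered without recomputation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .cohort import Cohort
from .econ import (BootstrapResult, BootstrapSettings, bootstrap_cua, ceac,
                   convert_currency, default_wtp_grid, verdict,
                   wtp_at_probability)
from .errors import AnalysisError
from .lifetable import LifeTable
from .qaly import EconParams, project_cohort, projected_gains
from .sensitivity import (SensitivityScenario, breakeven_limits,
                          default_scenarios, run_scenarios)

__all__ = ["run_cua", "GROUP_DEFS"]

# group label -> predicate on PatientRecord
GROUP_DEFS = {
    "all": lambda r: True,
    "age_70_79": lambda r: r.age_group == "70-79",
    "age_80_plus": lambda r: r.age_group == "80+",
    "scleral_buckle": lambda r: r.surgery_type == "scleral_buckle",
    "vitrectomy": lambda r: r.surgery_type == "vitrectomy",
}
SENSITIVITY_GROUPS = ("all", "age_70_79", "age_80_plus")


def _usd(amount: float, params: EconParams) -> int:
    return convert_currency(amount, params.exchange_rate_cny_per_usd)


def _group_payload(sub: Cohort, table: LifeTable, params: EconParams,
                   settings: BootstrapSettings, grid: np.ndarray,
                   include_replicates: bool) -> tuple[dict, BootstrapResult]:
    projections = project_cohort(sub, table, params)
    gains = projected_gains(projections)
    res = bootstrap_cua(sub.costs(), gains, settings)
    curve = ceac(res, grid)
    wtp_at = {}
    for p in (0.5, 0.7, 0.9):
        try:
            wtp_at[f"{p:.0%}"] = wtp_at_probability(curve, p)
        except AnalysisError:
            wtp_at[f"{p:.0%}"] = None

    upre = np.array([r.utility_pre for r in sub], float)
    u1y = np.array([r.utility_1y for r in sub], float)

    def sd(x):
        return float(np.std(x, ddof=1)) if x.size > 1 else None

    boot = {
        "mean_cost_cny": res.mean_cost,
        "mean_cost_usd": _usd(res.mean_cost, params),
        "cost_ci_cny": [res.cost_ci[0], res.cost_ci[1]],
        "cost_ci_usd": [_usd(res.cost_ci[0], params), _usd(res.cost_ci[1], params)],
        "mean_qaly_gain": res.mean_qaly,
        "qaly_ci": [res.qaly_ci[0], res.qaly_ci[1]],
        "mean_icer_cny_per_qaly": res.mean_icer,
        "mean_icer_usd_per_qaly": _usd(res.mean_icer, params)
        if np.isfinite(res.mean_icer) else None,
        "icer_of_means_cny_per_qaly": res.icer_of_means,
        "n_excluded_replicates": res.n_excluded,
    }
    if include_replicates:
        boot["replicates"] = {
            "delta_cost_cny": res.delta_cost.tolist(),
            "delta_qaly": res.delta_qaly.tolist(),
        }
    payload = {
        "n": len(sub),
        "utility_pre_mean": float(np.mean(upre)),
        "utility_pre_sd": sd(upre),
        "utility_1y_mean": float(np.mean(u1y)),
        "utility_1y_sd": sd(u1y),
        "utility_gain_mean": float(np.mean(u1y - upre)),
        "utility_gain_sd": sd(u1y - upre),
        "mean_life_expectancy_years": float(
            np.mean([p.life_expectancy for p in projections])),
        "bootstrap": boot,
        "verdict": verdict(res.mean_icer, params),
        "ceac": {
            "wtp_cny_per_qaly": curve.thresholds.tolist(),
            "probability": curve.probability.tolist(),
        },
        "wtp_at_probability": wtp_at,
    }
    return payload, res


def run_cua(cohort: Cohort, life_table: LifeTable, params: EconParams,
            settings: BootstrapSettings,
            wtp_grid: Optional[np.ndarray] = None,
            scenarios: Optional[list[SensitivityScenario]] = None,
            include_replicates: bool = True) -> dict:
    """Full cost-utility analysis; returns a JSON-serialisable dict.

    Every group and scenario uses the same bootstrap seed so rows are
    comparable; reruns with identical inputs are bit-for-bit identical.
    """
    cohort.require_nonempty("run_cua")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if scenarios is None:
        scenarios = default_scenarios()

    results: dict = {
        "config": {
            "discount_rate": params.discount_rate,
            "first_year_model": params.first_year_model,
            "gdp_per_capita_cny": params.gdp_per_capita_cny,
            "exchange_rate_cny_per_usd": params.exchange_rate_cny_per_usd,
            "wtp_threshold_cny_per_qaly": params.wtp_threshold_cny_per_qaly,
            "bootstrap": {
                "replications": settings.replications,
                "seed": settings.seed,
                "ci_lower": settings.ci_lower,
                "ci_upper": settings.ci_upper,
            },
        },
        "n_patients": len(cohort),
        "groups": {},
        "sensitivity": {},
    }

    baselines: dict[str, BootstrapResult] = {}
    subcohorts: dict[str, Cohort] = {}
    for name, pred in GROUP_DEFS.items():
        recs = [r for r in cohort if pred(r)]
        if not recs:
            continue
        sub = Cohort(recs, provenance=cohort.provenance, currency=cohort.currency)
        payload, res = _group_payload(sub, life_table, params, settings, grid,
                                      include_replicates)
        results["groups"][name] = payload
        baselines[name] = res
        subcohorts[name] = sub

    lam = params.wtp_threshold_cny_per_qaly
    for gname in SENSITIVITY_GROUPS:
        if gname not in baselines:
            continue
        sub = subcohorts[gname]
        sc_results = run_scenarios(sub, life_table, params, scenarios, settings,
                                   baseline=baselines[gname])
        rows = {}
        for label, sr in sc_results.items():
            rows[label] = {
                "n_patients": sr.n_patients,
                "mean_cost_cny": sr.result.mean_cost,
                "mean_qaly_gain": sr.result.mean_qaly,
                "mean_icer_cny_per_qaly": sr.result.mean_icer,
                "mean_icer_usd_per_qaly": _usd(sr.result.mean_icer, params)
                if np.isfinite(sr.result.mean_icer) else None,
            }
        base_icer = baselines[gname].mean_icer
        if np.isfinite(base_icer) and base_icer > 0:
            cost_lim, qaly_lim = breakeven_limits(base_icer, lam)
            breakeven = {"cost_increase_limit": cost_lim,
                         "qaly_decrease_limit": qaly_lim}
        else:
            breakeven = {"cost_increase_limit": None, "qaly_decrease_limit": None}
        results["sensitivity"][gname] = {"scenarios": rows, "breakeven": breakeven}

    return results
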