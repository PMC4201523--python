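"""Render analysis results into machine- and human-readable tables.

``render_report`` writes, into an output directory:

* ``results.json`` — the full results dict including replicate vectors
  (the audit trail); byte-identical across reruns with the same inputs.
* ``table_baseline_cua.csv`` — utilities, QALYs, costs and ICER per
  age group (the baseline cost-utility table).
* ``table_wtp_probability.csv`` — willingness-to-pay thresholds at
  50/70/90% acceptability per group.
* ``table_surgery_type.csv`` — the same economics per surgery type.
* ``table_sensitivity.csv`` — ICERs under the sensitivity battery plus
  analytic breakeven limits.
* ``ceac.csv`` — long-form (group, wtp, probability) CEAC data.
* ``report_notes.txt`` — formatting conventions (e.g. SDs suppressed
  for single observations).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cohort import SINGLE_OBS_SD_NOTE
from .errors import AnalysisError

__all__ = ["render_report"]

AGE_GROUPS = ["all", "age_70_79", "age_80_plus"]
SURGERY_GROUPS = ["scleral_buckle", "vitrectomy"]

BASELINE_ROWS = [
    ("n", lambda g: g["n"]),
    ("utility_pre_mean", lambda g: g["utility_pre_mean"]),
    ("utility_pre_sd", lambda g: g["utility_pre_sd"]),
    ("utility_1y_mean", lambda g: g["utility_1y_mean"]),
    ("utility_1y_sd", lambda g: g["utility_1y_sd"]),
    ("utility_gain_mean", lambda g: g["utility_gain_mean"]),
    ("utility_gain_sd", lambda g: g["utility_gain_sd"]),
    ("qalys_gained_mean", lambda g: g["bootstrap"]["mean_qaly_gain"]),
    ("qalys_gained_ci_lo", lambda g: g["bootstrap"]["qaly_ci"][0]),
    ("qalys_gained_ci_hi", lambda g: g["bootstrap"]["qaly_ci"][1]),
    ("mean_cost_cny", lambda g: g["bootstrap"]["mean_cost_cny"]),
    ("mean_cost_usd", lambda g: g["bootstrap"]["mean_cost_usd"]),
    ("cost_ci_lo_cny", lambda g: g["bootstrap"]["cost_ci_cny"][0]),
    ("cost_ci_hi_cny", lambda g: g["bootstrap"]["cost_ci_cny"][1]),
    ("mean_icer_cny_per_qaly", lambda g: g["bootstrap"]["mean_icer_cny_per_qaly"]),
    ("mean_icer_usd_per_qaly", lambda g: g["bootstrap"]["mean_icer_usd_per_qaly"]),
    ("verdict", lambda g: g["verdict"]),
]


def _table(groups: dict, names: list[str]) -> pd.DataFrame:
    cols = {}
    for name in names:
        if name not in groups:
            continue
        g = groups[name]
        cols[name] = {label: fn(g) for label, fn in BASELINE_ROWS}
    return pd.DataFrame(cols)


def render_report(results: dict, out_dir) -> list[Path]:
    """Write the report files; returns the paths written."""
    if not results or not results.get("groups"):
        raise AnalysisError("results object is empty; nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = out / "results.json"
    with open(path, "w") as fh:
        json.dump(results, fh, sort_keys=True, indent=1)
    written.append(path)

    groups = results["groups"]

    path = out / "table_baseline_cua.csv"
    _table(groups, AGE_GROUPS).to_csv(path, index_label="statistic")
    written.append(path)

    path = out / "table_wtp_probability.csv"
    wtp = {name: groups[name]["wtp_at_probability"]
           for name in AGE_GROUPS + SURGERY_GROUPS if name in groups}
    pd.DataFrame(wtp).to_csv(path, index_label="probability_cost_effective")
    written.append(path)

    path = out / "table_surgery_type.csv"
    _table(groups, SURGERY_GROUPS).to_csv(path, index_label="statistic")
    written.append(path)

    path = out / "table_sensitivity.csv"
    sens = results.get("sensitivity", {})
    cols = {}
    for gname, payload in sens.items():
        col = {label: row["mean_icer_cny_per_qaly"]
               for label, row in payload["scenarios"].items()}
        col["breakeven_cost_increase_limit"] = payload["breakeven"]["cost_increase_limit"]
        col["breakeven_qaly_decrease_limit"] = payload["breakeven"]["qaly_decrease_limit"]
        cols[gname] = col
    pd.DataFrame(cols).to_csv(path, index_label="scenario")
    written.append(path)

    path = out / "ceac.csv"
    frames = []
    for name, g in groups.items():
        frames.append(pd.DataFrame({
            "group": name,
            "wtp_cny_per_qaly": g["ceac"]["wtp_cny_per_qaly"],
            "probability_cost_effective": g["ceac"]["probability"],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    written.append(path)

    path = out / "report_notes.txt"
    path.write_text(
        SINGLE_OBS_SD_NOTE + "\n"
        "ICERs are means over bootstrap replicate ratios; the ratio of point "
        "means is reported separately in results.json as icer_of_means.\n"
        "USD figures use the fixed configured exchange rate, rounded half-up "
        "to whole dollars.\n"
    )
    written.append(path)
    return written
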