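"""Patient-level cohort container, CSV I/O and descriptive summaries.

The cohort CSV schema is fixed: one row per patient with demographics,
surgery descriptors, one-year direct costs in CNY, pre-operative and
one-year post-operative TTO utilities, and a logMAR visual-acuity
series (pre, 3 months, 1 year).  Costs cover all RRD-related direct
expenditure over the first year (pharmaceuticals, examinations,
treatment, anaesthesia, surgery, hospitalisation, transportation and
downstream complication costs); indirect costs are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .errors import AnalysisError, CohortValidationError, SchemaError

__all__ = [
    "PatientRecord",
    "Cohort",
    "SummaryTable",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "education_years",
    "surgery_type",
    "bilateral",
    "macula_off",
    "quadrants_detached",
    "symptom_duration_weeks",
    "bcva_pre_logmar",
    "bcva_3m_logmar",
    "bcva_1y_logmar",
    "utility_pre",
    "utility_1y",
    "cost_total_cny",
]

SEXES = ("male", "female")
SURGERY_TYPES = ("scleral_buckle", "vitrectomy")


@dataclass
class PatientRecord:
    """One patient's demographics, surgery descriptors, costs and outcomes."""

    patient_id: str
    age: int
    sex: str
    education_years: float
    surgery_type: str
    bilateral: bool
    macula_off: bool
    quadrants_detached: int
    symptom_duration_weeks: float
    bcva_pre_logmar: float
    bcva_3m_logmar: float
    bcva_1y_logmar: float
    utility_pre: float
    utility_1y: float
    cost_total_cny: float

    def problems(self) -> list[str]:
        """Invariant violations, as human-readable messages (empty = valid)."""
        out: list[str] = []
        if self.age < 60:
            out.append(f"age={self.age} below 60")
        if self.sex not in SEXES:
            out.append(f"sex={self.sex!r} not in {SEXES}")
        if self.education_years < 0:
            out.append(f"education_years={self.education_years} negative")
        if self.surgery_type not in SURGERY_TYPES:
            out.append(f"surgery_type={self.surgery_type!r} not in {SURGERY_TYPES}")
        if self.quadrants_detached not in (1, 2, 3, 4):
            out.append(f"quadrants_detached={self.quadrants_detached} not in 1..4")
        if self.symptom_duration_weeks < 0:
            out.append(f"symptom_duration_weeks={self.symptom_duration_weeks} negative")
        for name in ("bcva_pre_logmar", "bcva_3m_logmar", "bcva_1y_logmar"):
            v = getattr(self, name)
            if v < 0:
                out.append(f"{name}={v} negative")
        for name in ("utility_pre", "utility_1y"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                out.append(f"{name}={u} outside [0, 1]")
        if self.cost_total_cny < 0:
            out.append(f"cost_total_cny={self.cost_total_cny} negative")
        return out

    @property
    def utility_gain(self) -> float:
        return self.utility_1y - self.utility_pre

    @property
    def age_group(self) -> str:
        return "70-79" if self.age < 80 else "80+"


@dataclass
class Cohort:
    """Ordered collection of validated patient records."""

    records: list[PatientRecord]
    provenance: str = ""
    currency: str = "CNY"

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), set()
            for i in ids:
                (dup if i in seen else seen).add(i)
            raise CohortValidationError(f"duplicate patient_ids: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def require_nonempty(self, what: str = "analysis") -> None:
        if not self.records:
            raise AnalysisError(f"cohort is empty; cannot run {what}")

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in dc_fields(PatientRecord)]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.records],
                            columns=COHORT_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "",
                   strict: bool = True) -> "Cohort":
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort table missing required columns: {missing}")
        records: list[PatientRecord] = []
        n_dropped = 0
        for idx, row in df.iterrows():
            try:
                rec = _record_from_row(row)
                probs = rec.problems()
            except (ValueError, TypeError) as exc:
                rec, probs = None, [str(exc)]
            if probs:
                msg = f"row {idx} (patient_id={row.get('patient_id')!r}): " + "; ".join(probs)
                if strict:
                    raise CohortValidationError(msg)
                logger.warning("dropping invalid cohort row: %s", msg)
                n_dropped += 1
                continue
            records.append(rec)
        cohort = cls(records, provenance=provenance)
        cohort.n_dropped = n_dropped  # type: ignore[attr-defined]
        return cohort

    # --- convenience arrays used by the economic evaluation ---

    def costs(self) -> np.ndarray:
        return np.array([r.cost_total_cny for r in self.records], dtype=float)

    def utility_gains(self) -> np.ndarray:
        return np.array([r.utility_gain for r in self.records], dtype=float)


_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s not in _BOOL_MAP:
        raise ValueError(f"cannot parse boolean from {value!r}")
    return _BOOL_MAP[s]


def _record_from_row(row: pd.Series) -> PatientRecord:
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        age=int(row["age"]),
        sex=str(row["sex"]),
        education_years=float(row["education_years"]),
        surgery_type=str(row["surgery_type"]),
        bilateral=_parse_bool(row["bilateral"]),
        macula_off=_parse_bool(row["macula_off"]),
        quadrants_detached=int(row["quadrants_detached"]),
        symptom_duration_weeks=float(row["symptom_duration_weeks"]),
        bcva_pre_logmar=float(row["bcva_pre_logmar"]),
        bcva_3m_logmar=float(row["bcva_3m_logmar"]),
        bcva_1y_logmar=float(row["bcva_1y_logmar"]),
        utility_pre=float(row["utility_pre"]),
        utility_1y=float(row["utility_1y"]),
        cost_total_cny=float(row["cost_total_cny"]),
    )


def read_cohort(path, strict: bool = True) -> Cohort:
    """Read a cohort CSV.

    In strict mode any invariant violation aborts with an error naming
    the offending row and field.  In lenient mode offending rows are
    dropped, logged, and counted on the returned cohort's ``n_dropped``.
    """
    try:
        # round_trip float parsing: a write/read cycle must preserve values exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"cohort file {path} is empty") from exc
    return Cohort.from_frame(df, provenance=str(path), strict=strict)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort back to CSV with the standard column schema.

    Floats are written at full repr precision so a read/write round trip
    reproduces every field value exactly.
    """
    cohort.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

STRATA_RULES = ("age_group", "surgery_type", "none")

SINGLE_OBS_SD_NOTE = (
    "SD is reported as absent (blank) for strata with a single observation; "
    "a zero would overstate the precision of one measurement."
)


@dataclass
class SummaryTable:
    """Labelled descriptive statistics, overall and per stratum.

    ``data`` has one row per statistic and one column per stratum
    (``overall`` first).  No hypothesis tests are computed.
    """

    data: pd.DataFrame
    strata_rule: str
    footnotes: list[str] = field(default_factory=lambda: [SINGLE_OBS_SD_NOTE])

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="statistic")


def _sd(x: np.ndarray) -> float:
    # sample SD; a single observation has no dispersion estimate
    return float(np.std(x, ddof=1)) if x.size > 1 else float("nan")


def _stats_for(records: list[PatientRecord]) -> dict[str, float]:
    age = np.array([r.age for r in records], float)
    cost = np.array([r.cost_total_cny for r in records], float)
    upre = np.array([r.utility_pre for r in records], float)
    u1y = np.array([r.utility_1y for r in records], float)
    gain = u1y - upre
    b_pre = np.array([r.bcva_pre_logmar for r in records], float)
    b_3m = np.array([r.bcva_3m_logmar for r in records], float)
    b_1y = np.array([r.bcva_1y_logmar for r in records], float)
    dur = np.array([r.symptom_duration_weeks for r in records], float)
    return {
        "n_patients": float(len(records)),
        "age_mean": float(np.mean(age)),
        "age_sd": _sd(age),
        "male_prop": float(np.mean([r.sex == "male" for r in records])),
        "education_gt10y_prop": float(np.mean([r.education_years > 10 for r in records])),
        "symptom_duration_median_weeks": float(np.median(dur)),
        "gt2_quadrants_prop": float(np.mean([r.quadrants_detached > 2 for r in records])),
        "macula_off_prop": float(np.mean([r.macula_off for r in records])),
        "scleral_buckle_prop": float(np.mean([r.surgery_type == "scleral_buckle" for r in records])),
        "vitrectomy_prop": float(np.mean([r.surgery_type == "vitrectomy" for r in records])),
        "bilateral_prop": float(np.mean([r.bilateral for r in records])),
        "bcva_pre_mean": float(np.mean(b_pre)),
        "bcva_pre_sd": _sd(b_pre),
        "bcva_3m_mean": float(np.mean(b_3m)),
        "bcva_3m_sd": _sd(b_3m),
        "bcva_improvement_3m_mean": float(np.mean(b_pre - b_3m)),
        "bcva_improvement_3m_sd": _sd(b_pre - b_3m),
        "bcva_1y_mean": float(np.mean(b_1y)),
        "bcva_1y_sd": _sd(b_1y),
        "bcva_improvement_1y_mean": float(np.mean(b_pre - b_1y)),
        "bcva_improvement_1y_sd": _sd(b_pre - b_1y),
        "utility_pre_mean": float(np.mean(upre)),
        "utility_pre_sd": _sd(upre),
        "utility_1y_mean": float(np.mean(u1y)),
        "utility_1y_sd": _sd(u1y),
        "utility_gain_mean": float(np.mean(gain)),
        "utility_gain_sd": _sd(gain),
        "cost_mean_cny": float(np.mean(cost)),
        "cost_sd_cny": _sd(cost),
    }


def summarize_cohort(cohort: Cohort, strata: str = "age_group") -> SummaryTable:
    """Means, SDs, medians and proportions, overall and per stratum.

    ``strata`` is one of ``"age_group"`` (70-79 vs 80+), ``"surgery_type"``
    or ``"none"``.
    """
    cohort.require_nonempty("summarize_cohort")
    if strata not in STRATA_RULES:
        raise AnalysisError(f"unknown stratification rule {strata!r}; use one of {STRATA_RULES}")
    columns: dict[str, dict[str, float]] = {"overall": _stats_for(cohort.records)}
    if strata == "age_group":
        groups = {"70-79": [r for r in cohort if r.age_group == "70-79"],
                  "80+": [r for r in cohort if r.age_group == "80+"]}
    elif strata == "surgery_type":
        groups = {t: [r for r in cohort if r.surgery_type == t] for t in SURGERY_TYPES}
    else:
        groups = {}
    for label, recs in groups.items():
        if recs:
            columns[label] = _stats_for(recs)
    return SummaryTable(pd.DataFrame(columns), strata_rule=strata)
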