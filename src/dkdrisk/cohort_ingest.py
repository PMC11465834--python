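"""Cohort schema, eligibility screening, and outcome ascertainment.

This module owns the baseline-table column dictionary used throughout the
package, the MDRD estimate of glomerular filtration rate, the longitudinal-lab
event-ascertainment rule (two consecutive qualifying measurements separated by
at least 90 days), and the event-risk / event-rate summary arithmetic.

Baseline table schema (one row per patient)
-------------------------------------------
``patient_id`` plus the variables below. Continuous variables carry the units
stated; binary variables are 0/1; ``smoking`` is a single categorical column
with levels ``current`` / ``quit`` / ``never``.

=====================  =============================================
column                 meaning (units)
=====================  =============================================
age                    age at index date (years)
female                 female sex (0/1)
smoking                smoking status (current/quit/never)
heart_failure .. blindness   medical-history flags (0/1)
antihypertensive       antihypertensive drug use (0/1)
gla_non_insulin        non-insulin glucose-lowering agent use (0/1)
anticoagulant          anticoagulant use (0/1)
bmi                    body mass index (kg/m^2)
sbp, dbp               systolic / diastolic blood pressure (mmHg)
uacr                   urine albumin-to-creatinine ratio (mg/g)
egfr                   estimated GFR (mL/min/1.73 m^2)
scr                    serum creatinine (mg/dL)
hba1c                  glycated hemoglobin (%)
total_chol, ldl, hdl   cholesterol panel (mg/dL)
triglyceride           triglyceride (mg/dL)
hemoglobin             hemoglobin (g/dL)
wbc                    white blood cell count (10^9/L)
diabetes_duration      diabetes duration (years; defaults to 5)
=====================  =============================================

Longitudinal lab table schema (one row per measurement): ``patient_id``,
``day_from_index`` (int, days), ``analyte`` (``UACR`` mg/g, ``SCR`` mg/dL or
``EGFR`` mL/min/1.73 m^2), ``value``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

SMOKING_CATEGORIES = ("current", "quit", "never")

BASELINE_CONTINUOUS = (
    "age", "bmi", "sbp", "dbp", "uacr", "egfr", "scr", "hba1c",
    "total_chol", "ldl", "hdl", "triglyceride", "hemoglobin", "wbc",
    "diabetes_duration",
)

BASELINE_BINARY = (
    "female", "heart_failure", "stroke", "mi", "pvd", "retinopathy",
    "cataract", "amputation", "blindness", "antihypertensive",
    "gla_non_insulin", "anticoagulant",
)

BASELINE_CATEGORICAL = ("smoking",)

#: columns a risk-equation coefficient may refer to after encoding
ENCODED_PREDICTORS = (
    BASELINE_CONTINUOUS
    + BASELINE_BINARY
    + ("smoking_current", "smoking_quit", "smoking_never")
)

BASELINE_COLUMNS = ("patient_id",) + BASELINE_CONTINUOUS + BASELINE_BINARY + BASELINE_CATEGORICAL


class SchemaError(ValueError):
    """A required column is missing or malformed."""


def encode_predictors(baseline: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the smoking categorical expanded to 0/1 flags."""
    out = baseline.copy()
    if "smoking" in out.columns:
        for cat in SMOKING_CATEGORIES:
            out[f"smoking_{cat}"] = (out["smoking"] == cat).astype(float)
    return out


# ---------------------------------------------------------------------------
# MDRD estimated GFR
# ---------------------------------------------------------------------------

def mdrd_egfr(scr, age, female, black=False):
    """Estimated GFR (mL/min/1.73 m^2) from the 4-variable MDRD study equation.

    ``175 * scr^-1.154 * age^-0.203 * 0.742^female * 1.212^black``.
    Accepts scalars or numpy-compatible arrays; serum creatinine in mg/dL.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("serum creatinine and age must be positive")
    out = 175.0 * scr ** -1.154 * age ** -0.203
    out = out * np.where(np.asarray(female, dtype=bool), 0.742, 1.0)
    out = out * np.where(np.asarray(black, dtype=bool), 1.212, 1.0)
    return out if out.ndim else float(out)


def scr_from_egfr(egfr, age, female, black=False):
    """Invert :func:`mdrd_egfr`: the creatinine giving a target eGFR."""
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(egfr <= 0) or np.any(age <= 0):
        raise ValueError("eGFR and age must be positive")
    base = 175.0 * age ** -0.203
    base = base * np.where(np.asarray(female, dtype=bool), 0.742, 1.0)
    base = base * np.where(np.asarray(black, dtype=bool), 1.212, 1.0)
    out = (egfr / base) ** (-1.0 / 1.154)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Outcome definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeDefinition:
    """A lab-defined renal outcome.

    An event is ascertained from a *run* of consecutive qualifying
    measurements of ``analyte`` (values inside ``[lower, upper)``, adjacent in
    the patient's measurement sequence of that analyte — an intervening
    out-of-range value resets the run): the run must contain at least
    ``confirmations`` measurements and span at least ``min_gap_days`` from its
    first to its last measurement. The sparse-lab reading "two consecutive
    measurements separated by at least 90 days" is the special case of a
    two-measurement run; the run form extends it consistently to densely
    sampled series, where the confirming measurement 90+ days later has other
    qualifying measurements in between.
    """

    name: str
    analyte: str
    lower: float
    upper: float = math.inf
    min_gap_days: int = 90
    confirmations: int = 2

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")
        if self.min_gap_days < 0:
            raise ValueError("min_gap_days must be nonnegative")
        if self.confirmations < 1:
            raise ValueError("confirmations must be >= 1")

    def qualifies(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v >= self.lower) & (v < self.upper)


#: UACR 30-299 mg/g; UACR >= 300 mg/g; eGFR < 15 mL/min/1.73 m^2
MICROALBUMINURIA = OutcomeDefinition("microalbuminuria", "UACR", 30.0, 300.0)
MACROALBUMINURIA = OutcomeDefinition("macroalbuminuria", "UACR", 300.0)
RENAL_FAILURE = OutcomeDefinition("renal_failure", "EGFR", -math.inf, 15.0)

OUTCOME_DEFINITIONS: dict[str, OutcomeDefinition] = {
    d.name: d for d in (MICROALBUMINURIA, MACROALBUMINURIA, RENAL_FAILURE)
}


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EligibilityConfig:
    min_age: float = 18.0
    max_baseline_uacr: float = 30.0   # exclusive: baseline UACR must be < this
    min_baseline_egfr: float = 30.0   # inclusive: baseline eGFR must be >= this
    require_followup_lab: bool = True


def apply_eligibility(
    baseline: pd.DataFrame,
    labs: pd.DataFrame | None,
    config: EligibilityConfig = EligibilityConfig(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Screen a baseline table against the cohort-entry rules.

    Rules are applied in a fixed order — age >= 18, baseline UACR below 30,
    baseline eGFR at or above 30, no prior renal failure (a
    ``prior_renal_failure`` flag column, if present), at least one follow-up
    UACR or eGFR/creatinine measurement — and each exclusion is counted under
    the first rule the patient fails.

    Returns the eligible subset and an ordered exclusion ledger
    (reason -> count).
    """
    for col in ("patient_id", "age", "uacr", "egfr"):
        if col not in baseline.columns:
            raise SchemaError(f"baseline table lacks required column {col!r}")
    ledger: dict[str, int] = {}
    remaining = baseline

    def exclude(mask: pd.Series, reason: str):
        nonlocal remaining
        ledger[reason] = int(mask.sum())
        remaining = remaining[~mask]

    exclude(remaining["age"] < config.min_age, f"age < {config.min_age:g}")
    exclude(remaining["uacr"] >= config.max_baseline_uacr,
            f"baseline UACR >= {config.max_baseline_uacr:g}")
    exclude(remaining["egfr"] < config.min_baseline_egfr,
            f"baseline eGFR < {config.min_baseline_egfr:g}")
    if "prior_renal_failure" in remaining.columns:
        exclude(remaining["prior_renal_failure"].astype(bool), "prior renal failure")
    if config.require_followup_lab:
        if labs is None:
            raise SchemaError("eligibility requires the longitudinal lab table")
        has_lab = remaining["patient_id"].isin(
            labs.loc[labs["analyte"].isin(["UACR", "SCR", "EGFR"]), "patient_id"]
        )
        exclude(~has_lab, "no follow-up UACR/eGFR measurement")
    return remaining.reset_index(drop=True), ledger


# ---------------------------------------------------------------------------
# Event ascertainment
# ---------------------------------------------------------------------------

def derive_egfr(labs: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Append EGFR rows computed by MDRD from SCR rows (age/sex from baseline).

    Existing EGFR rows are left untouched; SCR rows without a matching
    baseline patient raise a schema error.
    """
    scr_rows = labs[labs["analyte"] == "SCR"]
    if scr_rows.empty:
        return labs
    info = baseline.set_index("patient_id")[["age", "female"]]
    missing = set(scr_rows["patient_id"]) - set(info.index)
    if missing:
        raise SchemaError(f"SCR measurements for patients absent from baseline: {sorted(missing)[:5]}")
    joined = scr_rows.merge(info, left_on="patient_id", right_index=True)
    egfr_rows = pd.DataFrame({
        "patient_id": joined["patient_id"],
        "day_from_index": joined["day_from_index"],
        "analyte": "EGFR",
        "value": mdrd_egfr(joined["value"].to_numpy(),
                           joined["age"].to_numpy(),
                           joined["female"].to_numpy().astype(bool)),
    })
    return pd.concat([labs, egfr_rows], ignore_index=True)


def ascertain_events(
    labs: pd.DataFrame,
    defn: OutcomeDefinition,
    patients: Iterable | None = None,
    horizon_years: float | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Ascertain one outcome for every patient from the longitudinal labs.

    Returns one row per patient: ``patient_id``, ``outcome``, ``occurred``,
    ``event_day`` (day of the FIRST measurement of the qualifying run; NaN if
    censored), ``censor_day`` (last measurement day of the defining analyte;
    NaN if event), ``followup_years``.

    Patients listed in ``patients`` but with no measurement of the defining
    analyte are censored at ``horizon_years`` (or rejected when ``strict``).
    Ascertainment ignores measurements of other analytes entirely.
    """
    sub = labs[labs["analyte"] == defn.analyte]
    sub = sub.sort_values(["patient_id", "day_from_index"], kind="stable")
    pid = sub["patient_id"].to_numpy()
    day = sub["day_from_index"].to_numpy(dtype=float)
    qual = defn.qualifies(sub["value"].to_numpy())

    frame = pd.DataFrame({"patient_id": pid, "day": day, "qual": qual})
    new_patient = frame["patient_id"].ne(frame["patient_id"].shift())
    run_id = (new_patient | frame["qual"].ne(frame["qual"].shift())).cumsum()
    runs = (frame[frame["qual"]]
            .groupby(run_id[frame["qual"]], sort=False)
            .agg(patient_id=("patient_id", "first"),
                 first_day=("day", "first"),
                 last_day=("day", "last"),
                 size=("day", "size")))
    hits = runs[(runs["size"] >= defn.confirmations)
                & (runs["last_day"] - runs["first_day"] >= defn.min_gap_days)]

    grouped = frame.groupby("patient_id", sort=False)
    last_day = grouped["day"].max()
    first_hit = hits.groupby("patient_id", sort=False)["first_day"].min()

    ids = last_day.index
    occurred = ids.isin(first_hit.index)
    event_day = first_hit.reindex(ids).to_numpy()
    censor_day = np.where(occurred, np.nan, last_day.to_numpy())
    records = pd.DataFrame({
        "patient_id": ids,
        "outcome": defn.name,
        "occurred": occurred,
        "event_day": event_day,
        "censor_day": censor_day,
    })

    if patients is not None:
        patients = pd.Index(patients)
        absent = patients.difference(ids)
        if len(absent):
            if strict:
                raise ValueError(
                    f"{len(absent)} patients have no {defn.analyte} measurements"
                )
            if horizon_years is None:
                raise ValueError(
                    "horizon_years is required to censor patients without measurements"
                )
            extra = pd.DataFrame({
                "patient_id": absent,
                "outcome": defn.name,
                "occurred": False,
                "event_day": np.nan,
                "censor_day": horizon_years * DAYS_PER_YEAR,
            })
            records = pd.concat([records, extra], ignore_index=True)
        records = records[records["patient_id"].isin(patients)]

    followup_days = np.where(records["occurred"], records["event_day"], records["censor_day"])
    records["followup_years"] = followup_days / DAYS_PER_YEAR
    return records.reset_index(drop=True)


def ascertain_event(series: pd.DataFrame, defn: OutcomeDefinition) -> dict:
    """Single-patient convenience wrapper around :func:`ascertain_events`."""
    if series.empty:
        raise ValueError("empty lab series")
    rec = ascertain_events(series, defn)
    if rec.empty:
        pid = series["patient_id"].iloc[0]
        last = float(series["day_from_index"].max())
        return {"patient_id": pid, "outcome": defn.name, "occurred": False,
                "event_day": None, "censor_day": last,
                "followup_years": last / DAYS_PER_YEAR}
    row = rec.iloc[0].to_dict()
    row["event_day"] = None if pd.isna(row["event_day"]) else float(row["event_day"])
    row["censor_day"] = None if pd.isna(row["censor_day"]) else float(row["censor_day"])
    return row


# ---------------------------------------------------------------------------
# Event risk / rate arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventStats:
    """Crude event summary for one outcome.

    ``event_risk`` is the percentage of patients with an event during
    follow-up; ``event_rate`` is events per 100 person-years.
    """

    outcome: str
    n_events: int
    n_patients: int
    person_years: float

    @property
    def event_risk(self) -> float:
        return 100.0 * self.n_events / self.n_patients

    @property
    def event_rate(self) -> float:
        return 100.0 * self.n_events / self.person_years

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_events": self.n_events,
            "n_patients": self.n_patients,
            "person_years": self.person_years,
            "event_rate_per_100py": self.event_rate,
            "event_risk_pct": self.event_risk,
        }


def event_stats_from_counts(outcome: str, n_events: int, n_patients: int,
                            person_years: float) -> EventStats:
    """Build an :class:`EventStats` directly from summary counts."""
    if n_patients <= 0 or person_years <= 0:
        raise ValueError("n_patients and person_years must be positive")
    return EventStats(outcome, int(n_events), int(n_patients), float(person_years))


def compute_event_stats(records: pd.DataFrame) -> list[EventStats]:
    """Summarize per-patient event records into per-outcome crude statistics."""
    out = []
    for outcome, grp in records.groupby("outcome", sort=False):
        out.append(event_stats_from_counts(
            outcome,
            int(grp["occurred"].sum()),
            len(grp),
            float(grp["followup_years"].sum()),
        ))
    return out
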