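"""Seeded synthetic type-2-diabetes cohorts with known ground-truth hazards.

The generator emulates the study population used to validate the renal risk
equations: baseline marginals matching the published cohort description
(means/SDs for continuous variables, prevalences for flags), exponential
proportional-hazards latent event times for the three renal outcomes, an EHR
style follow-up lab schedule whose values persistently cross the outcome
threshold after the latent event, independent exponential censoring per lab
stream, missing-completely-at-random cell deletion, and a seeded 2:1
validation/test split.

Ground truth (the per-outcome baseline hazards, log hazard ratios, and an
injected cumulative-hazard log-multiplier ``true_delta``) is returned
alongside the data so that recalibration can be tested by parameter recovery.

Continuous variables are drawn as independent truncated normals; the location
parameter is solved numerically so that the *truncated* mean equals the
profile mean (truncation would otherwise shift it). No between-variable
correlation is imposed by default (none is published); a correlation hook is
available for users who need it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_ingest import (
    DAYS_PER_YEAR,
    SMOKING_CATEGORIES,
    encode_predictors,
    scr_from_egfr,
)
from .risk_engine import RiskEquation


class ProfileError(ValueError):
    """A cohort profile or hazard spec fails validation."""


# ---------------------------------------------------------------------------
# Cohort profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContinuousSpec:
    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self):
        if self.sd < 0:
            raise ProfileError("SD must be nonnegative")
        if not self.low <= self.mean <= self.high:
            raise ProfileError("mean must lie inside the truncation range")


@dataclass(frozen=True)
class CohortProfile:
    """Marginal specification of a synthetic baseline cohort."""

    n_patients: int
    continuous: Mapping[str, ContinuousSpec]
    binary: Mapping[str, float]
    categorical: Mapping[str, Mapping[str, float]]
    follow_up_years: float = 7.0
    censor_rate_per_year: float = 0.0
    seed: int = 0
    correlation: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self):
        if self.n_patients < 10:
            raise ProfileError("n_patients must be >= 10")
        if self.follow_up_years <= 0:
            raise ProfileError("follow_up_years must be positive")
        if self.censor_rate_per_year < 0:
            raise ProfileError("censor_rate_per_year must be nonnegative")
        for name, p in self.binary.items():
            if not 0.0 <= p <= 1.0:
                raise ProfileError(f"prevalence for {name!r} outside [0, 1]")
        for name, levels in self.categorical.items():
            if abs(sum(levels.values()) - 1.0) > 1e-6:
                raise ProfileError(f"category probabilities for {name!r} must sum to 1")


# Default marginals: the published overall-cohort baseline description
# (n = 3,986; means (SD) for continuous variables, prevalences for flags).
# Truncation ranges are plausible physiologic bounds; UACR < 30 and
# eGFR >= 30 enforce cohort eligibility at baseline by construction.
_T1 = {
    "age": (63.08, 12.24, 18.0, 100.0),
    "bmi": (26.14, 3.13, 15.0, 45.0),
    "sbp": (127.28, 6.70, 90.0, 200.0),
    "dbp": (77.93, 5.21, 50.0, 120.0),
    "uacr": (11.93, 7.47, 0.3, 29.99),
    "egfr": (97.38, 33.67, 30.0, 220.0),
    "scr": (0.80, 0.29, 0.3, 3.0),
    "hba1c": (7.43, 1.40, 4.0, 15.0),
    "total_chol": (165.56, 35.94, 80.0, 350.0),
    "ldl": (101.19, 30.70, 30.0, 250.0),
    "hdl": (51.05, 14.71, 20.0, 120.0),
    "triglyceride": (135.37, 101.92, 30.0, 900.0),
    "hemoglobin": (13.09, 1.17, 8.0, 18.0),
    "wbc": (8.49, 1.64, 2.0, 20.0),
    "diabetes_duration": (5.0, 0.0, 5.0, 5.0),  # assumed 5 years for all
}

_T1_BINARY = {
    "female": 0.4496,
    "heart_failure": 0.0379,
    "stroke": 0.0562,
    "mi": 0.0193,
    "pvd": 0.0063,
    "retinopathy": 0.0354,
    "cataract": 0.0514,
    "amputation": 0.0005,
    "blindness": 0.0148,
    "antihypertensive": 0.6704,
    "gla_non_insulin": 0.9250,
    "anticoagulant": 0.0369,
}

_T1_SMOKING = {"current": 0.0424, "quit": 0.0286, "never": 0.9290}


def default_profile(n_patients: int = 3986, seed: int = 0,
                    censor_rate_per_year: float = 0.02,
                    follow_up_years: float = 7.0) -> CohortProfile:
    """The study-population profile with published baseline marginals."""
    return CohortProfile(
        n_patients=n_patients,
        continuous={k: ContinuousSpec(*v) for k, v in _T1.items()},
        binary=dict(_T1_BINARY),
        categorical={"smoking": dict(_T1_SMOKING)},
        follow_up_years=follow_up_years,
        censor_rate_per_year=censor_rate_per_year,
        seed=seed,
    )


@lru_cache(maxsize=256)
def _truncnorm_location(mean: float, sd: float, low: float, high: float) -> float:
    """Location mu such that a N(mu, sd) truncated to [low, high] has the
    requested mean."""
    if sd == 0:
        return mean

    def gap(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    lo, hi = mean - 8 * sd, mean + 8 * sd
    return optimize.brentq(gap, lo, hi, xtol=1e-9)


def generate_baseline(profile: CohortProfile) -> pd.DataFrame:
    """Draw a baseline table with the profile's marginals; seeded and pure."""
    rng = np.random.default_rng(profile.seed)
    n = profile.n_patients
    data: dict = {"patient_id": np.arange(1, n + 1)}
    for name, spec in profile.continuous.items():
        if spec.sd == 0:
            data[name] = np.full(n, spec.mean)
            continue
        loc = _truncnorm_location(spec.mean, spec.sd, spec.low, spec.high)
        a, b = (spec.low - loc) / spec.sd, (spec.high - loc) / spec.sd
        data[name] = stats.truncnorm.rvs(a, b, loc=loc, scale=spec.sd,
                                         size=n, random_state=rng)
    for name, p in profile.binary.items():
        data[name] = (rng.random(n) < p).astype(int)
    for name, levels in profile.categorical.items():
        cats = list(levels)
        probs = np.array([levels[c] for c in cats], dtype=float)
        data[name] = rng.choice(cats, size=n, p=probs / probs.sum())
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Ground-truth hazards and latent events
# ---------------------------------------------------------------------------

OUTCOMES = ("microalbuminuria", "macroalbuminuria", "renal_failure")

# Baseline yearly hazards solved from the published ~7-year crude event risks
# (35.65%, 5.97%, 0.90%): h = -ln(1 - risk)/7.
DEFAULT_BASE_HAZARDS = {
    "microalbuminuria": -math.log(1 - 0.3565) / 7.0,
    "macroalbuminuria": -math.log(1 - 0.0597) / 7.0,
    "renal_failure": -math.log(1 - 0.0090) / 7.0,
}


@dataclass(frozen=True)
class TrueHazardSpec:
    """Ground-truth exponential proportional-hazards data-generating process.

    ``true_delta`` is a log multiplier applied to every patient's cumulative
    hazard when *simulating* events but not when *predicting* from
    :meth:`to_equation` — exactly the miscalibration the recalibration
    estimator must recover.
    """

    base_hazard: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_HAZARDS))
    log_hr: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    centering: Mapping[str, float] = field(default_factory=dict)
    true_delta: float = 0.0

    def __post_init__(self):
        for k, h in self.base_hazard.items():
            if not (h > 0 and math.isfinite(h)):
                raise ProfileError(f"baseline hazard for {k!r} must be positive")
        for out, coefs in self.log_hr.items():
            for name, b in coefs.items():
                if not math.isfinite(b):
                    raise ProfileError(f"non-finite log-HR for {out}/{name}")
        if not math.isfinite(self.true_delta):
            raise ProfileError("true_delta must be finite")

    def rate(self, outcome: str, baseline: pd.DataFrame,
             with_delta: bool = True) -> np.ndarray:
        """Per-patient event rate h0 * exp(LP [+ delta])."""
        enc = encode_predictors(baseline)
        lp = np.zeros(len(baseline))
        for name, beta in self.log_hr.get(outcome, {}).items():
            lp += beta * (enc[name].to_numpy(dtype=float)
                          - self.centering.get(name, 0.0))
        if with_delta:
            lp = lp + self.true_delta
        return self.base_hazard[outcome] * np.exp(lp)

    def to_equation(self, outcome: str, horizon_years: float = 7.0,
                    name: str | None = None) -> RiskEquation:
        """The risk equation matching this process *without* ``true_delta``."""
        return RiskEquation(
            name=name or f"truth_{outcome}",
            outcome=outcome,
            family="exponential_ph",
            coefficients=dict(self.log_hr.get(outcome, {})),
            centering={k: self.centering[k]
                       for k in self.log_hr.get(outcome, {})
                       if k in self.centering},
            baseline={"rate": self.base_hazard[outcome]},
            horizon_years=horizon_years,
        )


def default_hazard_spec(true_delta: float = 0.0) -> TrueHazardSpec:
    """Study-condition hazards with mild, plausible covariate effects."""
    return TrueHazardSpec(
        log_hr={
            "microalbuminuria": {"hba1c": 0.08, "sbp": 0.01, "uacr": 0.02},
            "macroalbuminuria": {"hba1c": 0.10, "uacr": 0.03},
            "renal_failure": {"egfr": -0.02, "hba1c": 0.08},
        },
        centering={"hba1c": 7.43, "sbp": 127.28, "uacr": 11.93, "egfr": 97.38},
        true_delta=true_delta,
    )


def latent_event_records(
    baseline: pd.DataFrame,
    hazard: TrueHazardSpec,
    follow_up_years: float = 7.0,
    censor_rate_per_year: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Latent (perfectly observed) event records, one row per patient-outcome.

    Event times are exponential with each patient's true rate; censoring is
    independent exponential truncated at the administrative end of follow-up.
    Columns match the ascertainment output (``occurred``, ``followup_years``)
    plus the latent ``event_time_years`` and ``censor_time_years``.
    """
    rng = np.random.default_rng(seed)
    n = len(baseline)
    if n == 0:
        raise ProfileError("baseline table is empty")
    frames = []
    for outcome in hazard.base_hazard:
        rate = hazard.rate(outcome, baseline)
        t_event = np.where(rate > 0,
                           rng.exponential(1.0, n) / np.maximum(rate, 1e-300),
                           np.inf)
        if censor_rate_per_year > 0:
            t_cens = np.minimum(rng.exponential(1.0 / censor_rate_per_year, n),
                                follow_up_years)
        else:
            t_cens = np.full(n, follow_up_years)
        occurred = t_event <= t_cens
        frames.append(pd.DataFrame({
            "patient_id": baseline["patient_id"].to_numpy(),
            "outcome": outcome,
            "occurred": occurred,
            "event_time_years": t_event,
            "censor_time_years": t_cens,
            "followup_years": np.where(occurred, t_event, t_cens),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Follow-up lab trajectories
# ---------------------------------------------------------------------------

def generate_lab_trajectories(
    baseline: pd.DataFrame,
    hazard: TrueHazardSpec,
    visit_interval_days: int = 90,
    follow_up_years: float = 7.0,
    censor_rate_per_year: float = 0.0,
    seed: int = 0,
    jitter: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the follow-up lab table and return it with the latent truth.

    Visits occur on a fixed grid (day 0, then every ``visit_interval_days``)
    until the stream's censoring time. At each visit a UACR and a serum
    creatinine (SCR) value are recorded. Before any latent event the values
    stay on the sub-threshold side; from the first visit after the latent
    event time onward they persistently sit on the qualifying side with
    ``jitter`` relative spread, so the two-consecutive-measurements rule is
    the only event detector. Creatinine values are back-calculated from the
    intended eGFR via the MDRD equation using each patient's age and sex.

    Censoring is drawn independently for the UACR stream (micro/macro
    outcomes) and the creatinine stream (renal failure).

    Returns ``(labs, latent)``; ``latent`` has one row per patient-outcome
    with the latent event day and the stream censor day.
    """
    if visit_interval_days < 1:
        raise ProfileError("visit_interval_days must be >= 1")
    if len(baseline) == 0:
        raise ProfileError("baseline table is empty")
    rng = np.random.default_rng(seed)
    n = len(baseline)
    pid = baseline["patient_id"].to_numpy()
    age = baseline["age"].to_numpy(dtype=float)
    female = baseline["female"].to_numpy(dtype=bool)
    base_uacr = baseline["uacr"].to_numpy(dtype=float)
    base_egfr = baseline["egfr"].to_numpy(dtype=float)

    def draw_time(outcome):
        if outcome not in hazard.base_hazard:  # outcome not simulated
            return np.full(n, np.inf)
        rate = hazard.rate(outcome, baseline)
        return np.where(rate > 0,
                        rng.exponential(1.0, n) / np.maximum(rate, 1e-300),
                        np.inf)

    t_micro = draw_time("microalbuminuria")
    t_macro = draw_time("macroalbuminuria")
    t_rf = draw_time("renal_failure")

    def draw_censor():
        if censor_rate_per_year > 0:
            return np.minimum(rng.exponential(1.0 / censor_rate_per_year, n),
                              follow_up_years)
        return np.full(n, follow_up_years)

    cens_uacr = draw_censor()
    cens_scr = draw_censor()

    horizon_day = follow_up_years * DAYS_PER_YEAR
    grid = np.arange(0.0, horizon_day + 0.5, visit_interval_days)
    n_visits = len(grid)

    # visit mask per stream: visits strictly up to the stream censor day
    day_mat = np.broadcast_to(grid, (n, n_visits))
    uacr_keep = day_mat <= (cens_uacr * DAYS_PER_YEAR)[:, None]
    scr_keep = day_mat <= (cens_scr * DAYS_PER_YEAR)[:, None]

    year_mat = day_mat / DAYS_PER_YEAR
    post_micro = year_mat >= t_micro[:, None]
    post_macro = year_mat >= t_macro[:, None]
    post_rf = year_mat >= t_rf[:, None]

    # UACR values: macro >= 300, micro in [30, 300), else below 30
    z = rng.standard_normal((n, n_visits))
    val_macro = 300.0 * (1.0 + jitter * np.abs(z))
    val_micro = 30.0 * (1.0 + jitter * np.abs(z))          # <= ~45, safely < 300
    val_none = np.clip(base_uacr[:, None] * (1.0 + jitter * z), 0.1, 29.5)
    uacr_vals = np.where(post_macro, val_macro,
                         np.where(post_micro, val_micro, val_none))

    # eGFR targets: renal failure < 15, else near the baseline eGFR (>= 16)
    z2 = rng.standard_normal((n, n_visits))
    val_rf = 15.0 / (1.0 + jitter * np.abs(z2))
    val_ok = np.maximum(base_egfr[:, None] * (1.0 + 0.5 * jitter * z2), 16.0)
    egfr_vals = np.where(post_rf, val_rf, val_ok)
    scr_vals = scr_from_egfr(egfr_vals, age[:, None], female[:, None])

    rows_pid = np.repeat(pid, n_visits)
    rows_day = np.tile(grid, n).astype(int)
    uacr_df = pd.DataFrame({
        "patient_id": rows_pid[uacr_keep.ravel()],
        "day_from_index": rows_day[uacr_keep.ravel()],
        "analyte": "UACR",
        "value": uacr_vals.ravel()[uacr_keep.ravel()],
    })
    scr_df = pd.DataFrame({
        "patient_id": rows_pid[scr_keep.ravel()],
        "day_from_index": rows_day[scr_keep.ravel()],
        "analyte": "SCR",
        "value": scr_vals.ravel()[scr_keep.ravel()],
    })
    labs = pd.concat([uacr_df, scr_df], ignore_index=True)
    labs = labs.sort_values(["patient_id", "day_from_index", "analyte"],
                            kind="stable").reset_index(drop=True)

    latent = pd.concat([
        pd.DataFrame({
            "patient_id": pid, "outcome": outcome,
            "event_time_years": t,
            "censor_time_years": cens,
            "occurred": t <= cens,
        })
        for outcome, t, cens in (
            ("microalbuminuria", t_micro, cens_uacr),
            ("macroalbuminuria", t_macro, cens_uacr),
            ("renal_failure", t_rf, cens_scr),
        )
    ], ignore_index=True)
    return labs, latent


# ---------------------------------------------------------------------------
# Missingness and splitting
# ---------------------------------------------------------------------------

def inject_missingness(table: pd.DataFrame, rates: Mapping[str, float],
                       seed: int = 0) -> pd.DataFrame:
    """Delete cells completely at random at the requested per-column rates."""
    for col, r in rates.items():
        if not 0.0 <= r < 1.0:
            raise ProfileError(f"missingness rate for {col!r} must be in [0, 1)")
        if col not in table.columns:
            raise ProfileError(f"unknown column {col!r}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col, r in rates.items():
        if r == 0.0:
            continue
        mask = rng.random(len(out)) < r
        if out[col].dtype == object:
            out.loc[mask, col] = None
        else:
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


def split_cohort(table: pd.DataFrame, ratio: tuple[int, int] = (2, 1),
                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint, exhaustive split; floor(n * a/(a+b)) rows go first.

    With the default 2:1 ratio the first subset is the validation set and the
    second the test set.
    """
    if len(table) == 0:
        raise ProfileError("cannot split an empty table")
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ProfileError("ratio parts must be positive integers")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    n_first = int(len(table) * a / (a + b))
    first = table.iloc[np.sort(perm[:n_first])].reset_index(drop=True)
    second = table.iloc[np.sort(perm[n_first:])].reset_index(drop=True)
    return first, second
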