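"""Absolute-risk evaluation from configurable published-style risk equations.

Supports the three equation families used for diabetic-kidney-disease risk
prediction — a Cox equation with a reported baseline survival (RECODe-style),
and parametric proportional-hazards forms (exponential, Weibull and Gompertz,
covering UKPDS-OM2- and CHIME-style equations). All families share the
proportional-hazards identity

    risk(t) = 1 - exp(-H0(t) * exp(LP)),   LP = sum_j beta_j * (x_j - c_j)

with a family-specific baseline cumulative hazard H0(t):

    cox_baseline_survival : H0(t) = -ln S0(t)
    exponential_ph        : H0(t) = lambda * t
    weibull_ph            : H0(t) = lambda * t^rho
    gompertz_ph           : H0(t) = (lambda/phi) * (exp(phi*t) - 1)

Coefficient values shipped with the package are illustrative fixtures only;
real published equations are supplied by the user as registry files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_ingest import ENCODED_PREDICTORS, encode_predictors
from .imputation import pool_predictions

FAMILIES = ("cox_baseline_survival", "exponential_ph", "weibull_ph", "gompertz_ph")


class RegistryError(ValueError):
    """A risk-equation registry fails schema validation."""


@dataclass(frozen=True)
class RiskEquation:
    """A risk equation: family tag, coefficients, baseline parameters, horizon.

    ``coefficients`` maps predictor names to log hazard ratios; ``centering``
    gives reference values subtracted before exponentiation (empty -> raw
    predictors); ``baseline`` carries the family-specific parameters
    (``s0`` for Cox; ``rate`` and, where applicable, ``shape``); ``constants``
    declares predictor values to use when a column is absent from the cohort
    (e.g., ethnicity flags never collected in the target population).
    """

    name: str
    outcome: str
    family: str
    coefficients: Mapping[str, float]
    baseline: Mapping[str, float]
    centering: Mapping[str, float] = field(default_factory=dict)
    constants: Mapping[str, float] = field(default_factory=dict)
    horizon_years: float = 7.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise RegistryError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.horizon_years <= 0:
            raise RegistryError("horizon_years must be positive")
        known = set(ENCODED_PREDICTORS) | set(self.constants)
        unknown = sorted((set(self.coefficients) | set(self.centering)) - known)
        if unknown:
            raise RegistryError(f"unknown predictor names: {unknown}")
        if self.family == "cox_baseline_survival":
            s0 = self.baseline.get("s0")
            if s0 is None or not 0.0 < s0 <= 1.0:
                raise RegistryError("cox family requires baseline survival s0 in (0, 1]")
        else:
            rate = self.baseline.get("rate")
            if rate is None or rate <= 0:
                raise RegistryError(f"{self.family} requires a positive baseline 'rate'")
            if self.family in ("weibull_ph", "gompertz_ph"):
                shape = self.baseline.get("shape")
                if shape is None or shape <= 0:
                    raise RegistryError(f"{self.family} requires a positive 'shape'")

    # -- baseline cumulative hazard ------------------------------------
    def baseline_cumhaz(self, t: float | None = None) -> float:
        """H0(t) at the horizon (default) or at an arbitrary time t > 0."""
        t = self.horizon_years if t is None else float(t)
        if t <= 0:
            raise ValueError("time must be positive")
        b = self.baseline
        if self.family == "cox_baseline_survival":
            if t != self.horizon_years:
                raise ValueError(
                    "cox_baseline_survival provides S0 only at its horizon"
                )
            return -np.log(b["s0"])
        if self.family == "exponential_ph":
            return b["rate"] * t
        if self.family == "weibull_ph":
            return b["rate"] * t ** b["shape"]
        # gompertz_ph
        phi = b["shape"]
        return b["rate"] / phi * np.expm1(phi * t)


def load_equation(source: str | Path | Mapping) -> RiskEquation:
    """Load and validate a risk-equation registry (YAML/JSON file or mapping)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise RegistryError("registry must be a mapping")
    required = {"name", "outcome", "family", "coefficients", "baseline"}
    missing = sorted(required - set(raw))
    if missing:
        raise RegistryError(f"registry missing required keys: {missing}")
    try:
        return RiskEquation(
            name=str(raw["name"]),
            outcome=str(raw["outcome"]),
            family=str(raw["family"]),
            coefficients={k: float(v) for k, v in (raw["coefficients"] or {}).items()},
            baseline={k: float(v) for k, v in (raw["baseline"] or {}).items()},
            centering={k: float(v) for k, v in (raw.get("centering") or {}).items()},
            constants={k: float(v) for k, v in (raw.get("constants") or {}).items()},
            horizon_years=float(raw.get("horizon_years", 7.0)),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, RegistryError):
            raise
        raise RegistryError(str(exc)) from exc


def _predictor_matrix(eq: RiskEquation, data: pd.DataFrame) -> np.ndarray:
    cols = []
    for name in eq.coefficients:
        if name in data.columns:
            col = data[name].to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ValueError(
                    f"predictor {name!r} contains missing values; impute first"
                )
        elif name in eq.constants:
            col = np.full(len(data), eq.constants[name], dtype=float)
        else:
            raise ValueError(
                f"predictor {name!r} required by equation {eq.name!r} is absent"
            )
        cols.append(col)
    if not cols:
        return np.zeros((len(data), 0))
    return np.column_stack(cols)


def linear_predictor(eq: RiskEquation, data: pd.DataFrame | Mapping) -> np.ndarray | float:
    """Centered linear predictor sum_j beta_j * (x_j - c_j).

    ``data`` is a baseline table (or a single-patient mapping); the smoking
    categorical is expanded automatically. A missing predictor raises — it is
    never silently treated as zero.
    """
    scalar = not isinstance(data, pd.DataFrame)
    df = pd.DataFrame([data]) if scalar else data
    df = encode_predictors(df)
    x = _predictor_matrix(eq, df)
    beta = np.array([eq.coefficients[k] for k in eq.coefficients], dtype=float)
    center = np.array([eq.centering.get(k, 0.0) for k in eq.coefficients], dtype=float)
    lp = (x - center) @ beta
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    return float(lp[0]) if scalar else lp


def predict_risk(eq: RiskEquation, data: pd.DataFrame | Mapping, t: float | None = None):
    """Absolute event risk at the horizon for each patient.

    Proportional-hazards form 1 - exp(-H0(t) * exp(LP)); for the Cox family
    this is 1 - S0(t)^exp(LP).
    """
    lp = linear_predictor(eq, data)
    h0 = eq.baseline_cumhaz(t)
    risk = -np.expm1(-h0 * np.exp(lp))
    return risk


def predict_cohort(
    eq: RiskEquation,
    tables: pd.DataFrame | Sequence[pd.DataFrame],
    t: float | None = None,
) -> pd.Series:
    """Per-patient risks, pooled over multiply-imputed tables by averaging.

    Returns a Series indexed by ``patient_id`` in the row order of the (first)
    table.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not len(tables) or not len(tables[0]):
        raise ValueError("empty cohort")
    ids = tables[0]["patient_id"]
    per_imp = []
    for tab in tables:
        if not tab["patient_id"].equals(ids):
            raise ValueError("imputed tables must share patient order")
        per_imp.append(np.asarray(predict_risk(eq, tab, t)))
    pooled = pool_predictions(per_imp)
    return pd.Series(pooled, index=pd.Index(ids, name="patient_id"), name=eq.name)
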