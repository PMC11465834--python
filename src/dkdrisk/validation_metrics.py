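"""Discrimination and calibration diagnostics for absolute-risk predictions.

Discrimination is the Mann-Whitney concordance (AUROC). Calibration is
assessed by ranking patients into deciles of predicted risk and comparing the
per-decile mean predicted risk against the Kaplan-Meier observed risk at the
horizon: the ordinary-least-squares line through the ten (predicted,
observed) points gives the calibration slope and intercept, and the
Greenwood-Nam-D'Agostino (GND) chi-square

    X^2 = sum_g (O_g - P_g)^2 / VarGreenwood(O_g)

tests overall agreement against a chi-square with as many degrees of freedom
as contributing groups: the predictions being tested are fully prespecified
(external validation), so the group residuals are independent and no degree
of freedom is lost to in-sample estimation — under a perfectly calibrated
model the statistic's simulated null mean is the group count, and comparing
against groups-1 degrees of freedom roughly doubles the type-I error.
Groups with fewer than 5 events are merged with the adjacent lower decile
before the test, following standard GND practice.

The event flag used for AUROC is "event ascertained at any time during
follow-up"; patients censored early count as non-events. This matches the
crude event-risk definition used in the study design and is a documented
limitation (no censoring-weighted time-dependent AUROC is attempted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(risks, event_flags) -> float:
    """Mann-Whitney concordance: P(risk_event > risk_nonevent) + 0.5 P(tie)."""
    r = np.asarray(risks, dtype=float)
    y = np.asarray(event_flags).astype(bool)
    if r.shape != y.shape:
        raise MetricError("risks and event flags differ in length")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise MetricError("AUROC undefined: only one outcome class present")
    ranks = stats.rankdata(r)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# Kaplan-Meier with Greenwood variance
# ---------------------------------------------------------------------------

def km_risk(records: pd.DataFrame, horizon_years: float) -> tuple[float, float]:
    """Observed risk 1 - S_KM(horizon) and its Greenwood variance.

    ``records`` needs ``occurred`` and ``followup_years`` columns. Follow-up
    beyond the horizon is administratively censored at the horizon; at tied
    times events precede censorings. With no censoring before the horizon the
    result is exactly events/n with binomial variance p(1-p)/n.
    """
    if len(records) == 0:
        raise MetricError("empty group")
    t = records["followup_years"].to_numpy(dtype=float)
    d = records["occurred"].to_numpy().astype(bool)
    d = d & (t <= horizon_years)
    t = np.minimum(t, horizon_years)

    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    n = len(t)
    surv = 1.0
    gw = 0.0
    i = 0
    while i < n:
        tau = t[i]
        j = i
        dt = 0
        while j < n and t[j] == tau:
            dt += int(d[j])
            j += 1
        at_risk = n - i
        if dt > 0:
            surv *= 1.0 - dt / at_risk
            if at_risk > dt:
                gw += dt / (at_risk * (at_risk - dt))
            else:
                gw = np.inf  # S hits 0; variance degenerates
        i = j
    variance = 0.0 if surv == 0.0 else surv * surv * gw
    return 1.0 - surv, variance


def crude_risk(records: pd.DataFrame, horizon_years: float) -> tuple[float, float]:
    """Crude proportion with events ascertained by the horizon; binomial var."""
    if len(records) == 0:
        raise MetricError("empty group")
    t = records["followup_years"].to_numpy(dtype=float)
    d = records["occurred"].to_numpy().astype(bool) & (t <= horizon_years)
    p = d.mean()
    return float(p), float(p * (1 - p) / len(records))


# ---------------------------------------------------------------------------
# Decile calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    """Decile table plus slope/intercept, GND test, and AUROC."""

    deciles: pd.DataFrame
    slope: float
    intercept: float
    gnd_statistic: float
    gnd_df: int
    gnd_p: float
    auroc: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "gnd_statistic": self.gnd_statistic,
            "gnd_df": self.gnd_df,
            "gnd_p": self.gnd_p,
            "auroc": self.auroc,
            "deciles": self.deciles.to_dict(orient="records"),
        }


def calibration_line(deciles: pd.DataFrame) -> tuple[float, float]:
    """Unweighted OLS of observed (y) on mean predicted (x) group risks."""
    x = deciles["mean_predicted"].to_numpy(dtype=float)
    y = deciles["observed_risk"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise MetricError("degenerate calibration fit: fewer than 2 distinct group means")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def gnd_test(deciles: pd.DataFrame, min_events: int = 5) -> tuple[float, int, float]:
    """Greenwood-Nam-D'Agostino chi-square on a grouped calibration table.

    Needs columns ``n``, ``n_events``, ``mean_predicted``, ``observed_risk``,
    ``greenwood_var``. Groups with fewer than ``min_events`` events are merged
    into the adjacent lower group (the first group merges forward); merged
    observed risks are patient-count-weighted means and merged variances are
    n^2-weighted — exact for crude proportions, an approximation for KM under
    censoring. Zero-variance groups with zero residual contribute nothing but
    still count toward the degrees of freedom, which equal the number of
    usable groups (prespecified predictions; see the module docstring).
    """
    req = {"n", "n_events", "mean_predicted", "observed_risk", "greenwood_var"}
    if not req <= set(deciles.columns):
        raise MetricError(f"decile table lacks columns {sorted(req - set(deciles.columns))}")
    groups = deciles[list(req)].to_dict(orient="records")
    if len(groups) < 2:
        raise MetricError("GND test needs at least 2 groups")

    def merge(a, b):
        n = a["n"] + b["n"]
        wa, wb = a["n"] / n, b["n"] / n
        return {
            "n": n,
            "n_events": a["n_events"] + b["n_events"],
            "mean_predicted": wa * a["mean_predicted"] + wb * b["mean_predicted"],
            "observed_risk": wa * a["observed_risk"] + wb * b["observed_risk"],
            "greenwood_var": wa * wa * a["greenwood_var"] + wb * wb * b["greenwood_var"],
        }

    merged: list[dict] = []
    for g in groups:
        if merged and (g["n_events"] < min_events or merged[-1]["n_events"] < min_events):
            merged[-1] = merge(merged[-1], g)
        else:
            merged.append(dict(g))
    # trailing deficient group merges into its lower neighbour
    while len(merged) > 1 and merged[-1]["n_events"] < min_events:
        tail = merged.pop()
        merged[-1] = merge(merged[-1], tail)
    # zero-variance groups with a nonzero residual cannot stand alone either
    cleaned: list[dict] = []
    for g in merged:
        resid = g["observed_risk"] - g["mean_predicted"]
        if g["greenwood_var"] == 0.0 and resid != 0.0 and cleaned:
            cleaned[-1] = merge(cleaned[-1], g)
        else:
            cleaned.append(g)

    stat = 0.0
    usable = 0
    for g in cleaned:
        resid = g["observed_risk"] - g["mean_predicted"]
        if g["greenwood_var"] > 0.0:
            stat += resid * resid / g["greenwood_var"]
            usable += 1
        elif resid == 0.0:
            usable += 1
        else:
            raise MetricError("unmergeable zero-variance group with nonzero residual")
    df = max(usable, 1)
    p = float(stats.chi2.sf(stat, df))
    return float(stat), df, p


def decile_table(
    risks: pd.Series,
    records: pd.DataFrame,
    horizon_years: float,
    n_groups: int = 10,
    observed: str = "km",
) -> pd.DataFrame:
    """Group patients by predicted-risk decile and summarize each group.

    ``risks`` is indexed by patient id; ``records`` holds one row per patient
    (``patient_id``, ``occurred``, ``followup_years``). Ties at decile
    boundaries are broken by a stable sort on patient id. ``observed`` chooses
    the Kaplan-Meier ("km", default) or crude proportion ("crude") estimate.
    """
    rec = records.set_index("patient_id")
    if not risks.index.isin(rec.index).all():
        raise MetricError("risks contain patients absent from event records")
    rec = rec.loc[risks.index]
    est = {"km": km_risk, "crude": crude_risk}[observed]

    df = pd.DataFrame({
        "patient_id": risks.index,
        "risk": risks.to_numpy(dtype=float),
        "occurred": rec["occurred"].to_numpy(),
        "followup_years": rec["followup_years"].to_numpy(dtype=float),
    }).sort_values(["risk", "patient_id"], kind="stable")

    rows = []
    for gi, idx in enumerate(np.array_split(np.arange(len(df)), n_groups), start=1):
        chunk = df.iloc[idx]
        obs, var = est(chunk, horizon_years)
        within = chunk["occurred"].to_numpy().astype(bool) & (
            chunk["followup_years"].to_numpy() <= horizon_years)
        rows.append({
            "decile": gi,
            "n": len(chunk),
            "n_events": int(within.sum()),
            "mean_predicted": float(chunk["risk"].mean()),
            "observed_risk": obs,
            "greenwood_var": var,
        })
    return pd.DataFrame(rows)


def decile_calibration(
    risks: pd.Series,
    records: pd.DataFrame,
    horizon_years: float,
    n_groups: int = 10,
    observed: str = "km",
    strict_line: bool = True,
) -> CalibrationReport:
    """Full calibration report: decile table, OLS line, GND test, AUROC.

    With ``strict_line=False`` a degenerate line fit (e.g. a constant-risk
    equation) yields NaN slope/intercept instead of raising, so that the
    AUROC and GND components are still reported.
    """
    if len(risks) < 20:
        raise MetricError("decile calibration needs at least 20 patients")
    table = decile_table(risks, records, horizon_years, n_groups, observed)
    try:
        slope, intercept = calibration_line(table)
    except MetricError:
        if strict_line:
            raise
        slope = intercept = float("nan")
    stat, df, p = gnd_test(table)
    rec = records.set_index("patient_id").loc[risks.index]
    auc = auroc(risks.to_numpy(dtype=float), rec["occurred"].to_numpy())
    return CalibrationReport(table, slope, intercept, stat, df, p, auc)
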