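"""Multiple imputation by fully conditional specification (chained equations).

Continuous targets are filled by predictive mean matching (PMM): an ordinary
least-squares model predicts the target from every other baseline variable and
each missing cell receives the *observed* value of one of the ``pmm_donors``
donors whose predicted means are nearest. Categorical targets are filled by a
multinomial-logistic draw. The chain is initialized from column medians/modes
and cycled ``n_iterations`` times; ``n_imputations`` independent chains give
the completed tables. Downstream, per-imputation risk predictions are pooled
by the element-wise arithmetic mean (point predictions only — no Rubin
variance pooling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression


@dataclass(frozen=True)
class ImputationConfig:
    n_imputations: int = 5
    n_iterations: int = 10
    pmm_donors: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_imputations < 1 or self.n_iterations < 1 or self.pmm_donors < 1:
            raise ValueError("imputation config values must be positive")


class UnimputableColumnError(ValueError):
    pass


def _design(df: pd.DataFrame, cols: Sequence[str], cat_cols: set[str]) -> np.ndarray:
    """Numeric design matrix (intercept + predictors, categoricals one-hot)."""
    parts = [np.ones((len(df), 1))]
    for c in cols:
        if c in cat_cols:
            dummies = pd.get_dummies(df[c])
            parts.append(dummies.to_numpy(dtype=float)[:, :-1])
        else:
            parts.append(df[c].to_numpy(dtype=float)[:, None])
    return np.hstack(parts)


def _pmm_fill(pred_obs, y_obs, pred_mis, donors, rng):
    """For each missing prediction, draw one of the nearest observed donors."""
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_y = y_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    n = len(sorted_pred)
    fills = np.empty(len(pred_mis))
    for i, p in enumerate(pos):
        lo = max(0, min(p - donors, n - 2 * donors))
        hi = min(n, lo + 2 * donors)
        window = np.arange(lo, hi)
        dist = np.abs(sorted_pred[window] - pred_mis[i])
        nearest = window[np.argsort(dist, kind="stable")[:donors]]
        fills[i] = sorted_y[rng.choice(nearest)]
    return fills


def impute_fcs(
    table: pd.DataFrame,
    config: ImputationConfig = ImputationConfig(),
    categorical: Sequence[str] | None = None,
    id_col: str = "patient_id",
    return_log: bool = False,
):
    """Return ``n_imputations`` completed copies of ``table``.

    Observed cells are never altered; PMM fills are always observed donor
    values from the same column. ``categorical`` defaults to the
    object/category-dtype columns. Deterministic given ``config.seed``.
    """
    df = table.copy()
    model_cols = [c for c in df.columns if c != id_col]
    cat_cols = set(categorical) if categorical is not None else {
        c for c in model_cols if df[c].dtype == object or str(df[c].dtype) == "category"
    }
    miss_mask = df[model_cols].isna()
    miss_cols = [c for c in model_cols if miss_mask[c].any()]

    for c in miss_cols:
        n_obs = (~miss_mask[c]).sum()
        if n_obs == 0:
            raise UnimputableColumnError(f"column {c!r} has no observed values")
        if c not in cat_cols and n_obs < config.pmm_donors:
            raise UnimputableColumnError(
                f"column {c!r} has only {n_obs} observed values (< pmm_donors)"
            )

    log: dict = {
        "columns": {
            c: {"n_filled": int(miss_mask[c].sum()),
                "donor_pool": int((~miss_mask[c]).sum())}
            for c in miss_cols
        },
        "chain_means": [],
    }

    if not miss_cols:
        tables = [df.copy() for _ in range(config.n_imputations)]
        return (tables, log) if return_log else tables

    root = np.random.SeedSequence(config.seed)
    completed = []
    for child in root.spawn(config.n_imputations):
        rng = np.random.default_rng(child)
        work = df.copy()
        # initialize by median / mode
        for c in miss_cols:
            if c in cat_cols:
                fill = work[c].mode(dropna=True).iloc[0]
            else:
                fill = work[c].median(skipna=True)
            work.loc[miss_mask[c], c] = fill
        chain = []
        for _ in range(config.n_iterations):
            for c in miss_cols:
                others = [o for o in model_cols if o != c]
                X = _design(work, others, cat_cols)
                obs = ~miss_mask[c].to_numpy()
                if c in cat_cols:
                    y_obs = work.loc[obs, c].to_numpy()
                    if len(np.unique(y_obs)) == 1:
                        work.loc[~obs, c] = y_obs[0]
                        continue
                    # standardize for a well-conditioned lbfgs fit
                    mu, sd = X.mean(axis=0), X.std(axis=0)
                    sd[sd == 0] = 1.0
                    Xs = (X - mu) / sd
                    clf = LogisticRegression(max_iter=500)
                    clf.fit(Xs[obs], y_obs)
                    proba = clf.predict_proba(Xs[~obs])
                    cum = np.cumsum(proba, axis=1)
                    u = rng.random(len(proba))[:, None]
                    picks = (u > cum).sum(axis=1)
                    work.loc[~obs, c] = clf.classes_[picks]
                else:
                    y = work[c].to_numpy(dtype=float)
                    beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
                    pred = X @ beta
                    fills = _pmm_fill(pred[obs], y[obs], pred[~obs],
                                      config.pmm_donors, rng)
                    col = work[c].to_numpy(dtype=float)
                    col[~obs] = fills
                    work[c] = col
            chain.append({c: float(np.asarray(work[c], dtype=float).mean())
                          for c in miss_cols if c not in cat_cols})
        log["chain_means"].append(chain)
        completed.append(work)
    return (completed, log) if return_log else completed


def pool_predictions(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Pool per-imputation risk vectors by the element-wise arithmetic mean."""
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    if not arrs:
        raise ValueError("no prediction vectors to pool")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("prediction vectors differ in length")
    pooled = np.mean(arrs, axis=0)
    if np.any(pooled < 0) or np.any(pooled > 1):
        raise ValueError("pooled risks fall outside [0, 1]")
    return pooled
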