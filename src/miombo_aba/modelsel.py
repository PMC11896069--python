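"""Predictor screening, best-subsets selection, and log-linear fitting.

The response (a plot attribute such as AGB) is modelled on the natural
log scale as a linear function of lidar metrics. Model search follows
the classic small-sample inventory recipe:

1. drop one of every pair of predictors whose absolute Pearson
   correlation exceeds a threshold (default 0.85), keeping the member
   more correlated with the response;
2. enumerate all predictor subsets up to a maximum size, scoring each
   OLS fit with R^2, adjusted R^2, predicted R^2 (leave-one-out PRESS),
   Mallows' Cp, AICc and BIC;
3. select by minimum AICc, preferring smaller subsets on near-ties;
4. fit the chosen subset to ln(y) and predict on the original scale by
   exponentiation with the lognormal bias-correction factor
   CF = exp(MSE/2).

AICc and BIC use the Gaussian-likelihood forms
``AICc = n ln(SSE/n) + 2k + 2k(k+1)/(n-k-1)`` and
``BIC = n ln(SSE/n) + k ln(n)`` with ``k = p + 2`` parameters
(slopes, intercept and error variance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def screen_collinear(
    metric_table: pd.DataFrame,
    response: pd.Series | np.ndarray,
    r_threshold: float = 0.85,
) -> list[str]:
    """Drop one member of each collinear predictor pair.

    Constant columns (and all-NaN columns) are removed first. Remaining
    pairs with |r| above the threshold are resolved in descending order
    of |r| (alphabetical tie-break); the member with the smaller absolute
    correlation to the response is dropped (alphabetically later name on
    a tie). Deterministic by construction. Returns retained names in the
    table's column order.
    """
    y = np.asarray(response, dtype=float)
    cols = [
        c
        for c in metric_table.columns
        if metric_table[c].notna().all() and metric_table[c].std() > 0
    ]
    if not cols:
        raise ValueError("all predictors are constant or missing")
    data = {c: metric_table[c].to_numpy(dtype=float) for c in cols}
    resp_corr = {c: abs(_pearson(data[c], y)) for c in cols}
    alive = set(cols)
    while True:
        pairs = [
            (abs(_pearson(data[a], data[b])), a, b)
            for a, b in combinations(sorted(alive), 2)
        ]
        pairs = [p for p in pairs if p[0] > r_threshold]
        if not pairs:
            break
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        _, a, b = pairs[0]
        if resp_corr[a] > resp_corr[b]:
            alive.discard(b)
        elif resp_corr[b] > resp_corr[a]:
            alive.discard(a)
        else:
            alive.discard(max(a, b))
    return [c for c in cols if c in alive]


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares with intercept: returns (beta, residuals, SSE)."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, resid, float(resid @ resid)


@dataclass
class ModelCandidate:
    predictors: tuple[str, ...]
    r2: float
    adj_r2: float
    pred_r2: float
    cp: float
    aicc: float
    bic: float

    @property
    def size(self) -> int:
        return len(self.predictors)


def enumerate_subsets(
    metric_table: pd.DataFrame,
    ln_response: pd.Series | np.ndarray,
    max_size: int = 7,
    predictors: list[str] | None = None,
) -> list[ModelCandidate]:
    """Exhaustive best-subsets search, ranked by AICc.

    Scores every subset of size 1..max_size of the (screened) predictor
    columns against the ln-scale response. Candidates are returned
    sorted by AICc ascending with ties going to the smaller subset, then
    alphabetically. Subsets with non-positive AICc degrees of freedom
    (n - k - 1 <= 0) are skipped; a perfect fit (SSE = 0) is reported
    with AICc/BIC of -inf.
    """
    if predictors is None:
        predictors = list(metric_table.columns)
    y = np.asarray(ln_response, dtype=float)
    n = y.size
    if n <= max_size + 3:
        max_size = max(n - 4, 1)
    sst = float(((y - y.mean()) ** 2).sum())
    cols = {c: metric_table[c].to_numpy(dtype=float) for c in predictors}

    # full-model residual variance anchors Mallows' Cp
    mse_full = np.nan
    if n - len(predictors) - 1 > 0:
        _, _, sse_full = _ols(np.column_stack([cols[c] for c in predictors]), y)
        dof_full = n - len(predictors) - 1
        if sse_full > 0 and dof_full > 0:
            mse_full = sse_full / dof_full

    out: list[ModelCandidate] = []
    for size in range(1, max_size + 1):
        k = size + 2
        if n - k - 1 <= 0:
            continue
        for subset in combinations(predictors, size):
            X = np.column_stack([cols[c] for c in subset])
            A = np.column_stack([np.ones(n), X])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ beta
            sse = float(resid @ resid)
            r2 = 1.0 - sse / sst if sst > 0 else np.nan
            dof = n - size - 1
            adj = 1.0 - (1.0 - r2) * (n - 1) / dof if sst > 0 else np.nan
            # leave-one-out PRESS via the hat matrix
            try:
                H = A @ np.linalg.solve(A.T @ A, A.T)
                h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
                press = float(((resid / (1.0 - h)) ** 2).sum())
                pred_r2 = 1.0 - press / sst if sst > 0 else np.nan
            except np.linalg.LinAlgError:
                pred_r2 = np.nan
            cp = sse / mse_full + 2 * (size + 1) - n if np.isfinite(mse_full) else np.nan
            if sse > 0:
                aicc = n * np.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
                bic = n * np.log(sse / n) + k * np.log(n)
            else:
                aicc = bic = -np.inf
            out.append(ModelCandidate(subset, r2, adj, pred_r2, cp, float(aicc), float(bic)))
    out.sort(key=lambda c: (c.aicc, c.size, c.predictors))
    return out


def candidates_to_frame(candidates: list[ModelCandidate]) -> pd.DataFrame:
    """Candidate list as a table: one row per subset with scores and members."""
    rows = [
        {
            "vars": c.size,
            "R2": c.r2,
            "R2_adj": c.adj_r2,
            "R2_pred": c.pred_r2,
            "Cp": c.cp,
            "AICc": c.aicc,
            "BIC": c.bic,
            "predictors": "+".join(c.predictors),
        }
        for c in candidates
    ]
    return pd.DataFrame(rows)


@dataclass
class FittedModel:
    """An ln-scale OLS model with its back-transform correction."""

    response: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    mse: float
    site: str = ""
    n: int = 0
    fit_r2: float = np.nan
    fit_adj_r2: float = np.nan

    @property
    def correction_factor(self) -> float:
        return float(np.exp(self.mse / 2.0))

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "intercept": self.intercept,
            "coefficients": [float(v) for v in self.coefficients],
            "mse": self.mse,
            "correction_factor": self.correction_factor,
            "site": self.site,
            "n": self.n,
            "fit_r2": self.fit_r2,
            "fit_adj_r2": self.fit_adj_r2,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            d["response"], tuple(d["predictors"]), d["intercept"],
            np.asarray(d["coefficients"], dtype=float), d["mse"], d.get("site", ""),
            d.get("n", 0), d.get("fit_r2", np.nan), d.get("fit_adj_r2", np.nan),
        )

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_log_mlr(
    metric_table: pd.DataFrame,
    response_values: pd.Series | np.ndarray,
    subset: tuple[str, ...] | list[str],
    response_name: str = "y",
    site: str = "",
) -> FittedModel:
    """OLS of ln(response) on the given predictor subset.

    Residual MSE uses the unbiased denominator n - p - 1; the
    back-transform correction factor is exp(MSE/2).
    """
    y = np.asarray(response_values, dtype=float)
    if (y <= 0).any():
        bad = np.flatnonzero(y <= 0)
        idx = list(metric_table.index[bad[:5]]) if len(metric_table) == y.size else bad[:5]
        raise ValueError(f"non-positive response for plots {idx}; cannot log-transform")
    subset = tuple(subset)
    n, p = y.size, len(subset)
    if n <= p + 2:
        raise ValueError(f"too few observations (n={n}) for {p} predictors")
    X = metric_table[list(subset)].to_numpy(dtype=float)
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError(f"rank-deficient design for subset {subset}")
    lny = np.log(y)
    beta, resid, sse = _ols(X, lny)
    mse = sse / (n - p - 1)
    sst = float(((lny - lny.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if sst > 0 else np.nan
    return FittedModel(response_name, subset, float(beta[0]), beta[1:], mse, site, n,
                       r2, adj)


def predict_attribute(model: FittedModel, metric_rows: pd.DataFrame) -> np.ndarray:
    """Original-scale predictions: exp(ln-scale fit) x exp(MSE/2)."""
    missing = [c for c in model.predictors if c not in metric_rows.columns]
    if missing:
        raise KeyError(f"metric table missing model predictors {missing}")
    X = metric_rows[list(model.predictors)].to_numpy(dtype=float)
    lin = model.intercept + X @ model.coefficients
    return np.exp(lin) * model.correction_factor


def select_and_fit(
    metric_table: pd.DataFrame,
    response_values: pd.Series | np.ndarray,
    response_name: str = "y",
    site: str = "",
    r_threshold: float = 0.85,
    max_size: int = 7,
) -> tuple[FittedModel, list[ModelCandidate], list[str]]:
    """Screen, enumerate, and fit the minimum-AICc subset in one call."""
    y = np.asarray(response_values, dtype=float)
    retained = screen_collinear(metric_table, np.log(y), r_threshold)
    candidates = enumerate_subsets(metric_table[retained], np.log(y), max_size)
    if not candidates:
        raise ValueError("no admissible candidate subsets")
    best = candidates[0]
    model = fit_log_mlr(metric_table, y, best.predictors, response_name, site)
    return model, candidates, retained
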