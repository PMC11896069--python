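"""Error statistics, pooled k-fold cross-validation, and model transfer.

For observed attributes y_i and predictions yhat_i over n plots:

    RMSE  = sqrt( sum (y_i - yhat_i)^2 / n )
    Bias  = sum (yhat_i - y_i) / n
    rRMSE = 100 * RMSE / mean(y)        (per cent)
    rBias = 100 * Bias / mean(y)        (per cent)

The relative statistics are normalised by the mean *observed* attribute
by default; ``relative_denominator='predicted'`` switches to the mean
prediction. R^2 is the squared Pearson correlation of observed versus
predicted.

Cross-validation follows the pooled-fold convention: the data are
randomly split into k near-equal folds, each fold is predicted by a
model fitted on the remainder, the n out-of-fold predictions are pooled
into one table, and the statistics above are applied once to that table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modelsel import FittedModel, fit_log_mlr, predict_attribute


@dataclass
class EvaluationResult:
    n: int
    rmse: float
    rrmse_pct: float
    bias: float
    rbias_pct: float
    r2: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "RMSE": self.rmse,
            "rRMSE_pct": self.rrmse_pct,
            "Bias": self.bias,
            "rBias_pct": self.rbias_pct,
            "R2": self.r2,
        }


def evaluate_predictions(
    observed,
    predicted,
    relative_denominator: str = "observed",
) -> EvaluationResult:
    """Accuracy statistics for a table of observed vs predicted values."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} observed vs {yhat.size} predicted")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    n = y.size
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    bias = float(np.mean(yhat - y))
    if relative_denominator == "observed":
        denom = float(y.mean())
    elif relative_denominator == "predicted":
        denom = float(yhat.mean())
    else:
        raise ValueError(f"unknown relative_denominator {relative_denominator!r}")
    if denom == 0:
        raise ValueError("mean attribute is zero; relative statistics undefined")
    sy, syh = y.std(), yhat.std()
    r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2) if sy > 0 and syh > 0 else np.nan
    return EvaluationResult(n, rmse, 100.0 * rmse / denom, bias, 100.0 * bias / denom, r2)


def kfold_cv(
    metric_table: pd.DataFrame,
    response_values,
    subset,
    k: int = 10,
    seed: int = 0,
    response_name: str = "y",
    relative_denominator: str = "observed",
) -> tuple[EvaluationResult, pd.DataFrame]:
    """Pooled k-fold cross-validation of one ln-scale model.

    Returns the pooled evaluation and the pooled observed/predicted
    table (indexed like ``metric_table``, with the fold assignment).
    Fold sizes differ by at most one; each observation is predicted
    exactly once.
    """
    y = np.asarray(response_values, dtype=float)
    n = y.size
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n]; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    pred = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    for fi, test_idx in enumerate(folds):
        train = np.setdiff1d(perm, test_idx)
        try:
            model = fit_log_mlr(
                metric_table.iloc[train], y[train], subset, response_name
            )
        except ValueError as err:
            raise ValueError(f"fold {fi}: {err}") from err
        pred[test_idx] = predict_attribute(model, metric_table.iloc[test_idx])
        fold_of[test_idx] = fi
    table = pd.DataFrame(
        {"observed": y, "predicted": pred, "fold": fold_of}, index=metric_table.index
    )
    return evaluate_predictions(y, pred, relative_denominator), table


def transfer_model(
    model: FittedModel,
    metric_table_target: pd.DataFrame,
    responses_target,
    relative_denominator: str = "observed",
) -> tuple[EvaluationResult, pd.DataFrame]:
    """Apply a fitted model to another site's plots without refitting."""
    pred = predict_attribute(model, metric_table_target)
    y = np.asarray(responses_target, dtype=float)
    table = pd.DataFrame(
        {"observed": y, "predicted": pred}, index=metric_table_target.index
    )
    return evaluate_predictions(y, pred, relative_denominator), table


def plot_observed_vs_predicted(table: pd.DataFrame, path, title: str = "",
                               units: str = "") -> None:
    """Scatter of observed vs predicted with the 1:1 line, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = table["observed"].to_numpy(dtype=float)
    yhat = table["predicted"].to_numpy(dtype=float)
    lim = (0.0, 1.05 * max(y.max(), yhat.max()))
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(y, yhat, s=18, alpha=0.8, edgecolor="k", linewidth=0.3)
    ax.plot(lim, lim, "k--", linewidth=0.8)
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    label = f" ({units})" if units else ""
    ax.set_xlabel(f"field estimate{label}")
    ax.set_ylabel(f"lidar estimate{label}")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
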