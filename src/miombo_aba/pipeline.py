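"""One-command study pipeline: simulate -> preprocess -> metrics -> models.

Ties the modules together the way the underlying study design does: two
sites of circular field plots, per-site ("site-specific") models, a
pooled ("combined") model, and cross-site transfer of each site model to
the other site, all evaluated with pooled k-fold cross-validation and
the RMSE/Bias family of statistics.

All randomness flows from a single root seed, split per stage with
``numpy.random.SeedSequence`` so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evalstats import evaluate_predictions, kfold_cv, transfer_model
from .fieldcalc import AllometryParams, plot_attribute_table
from .metrics import PlotDefinition, clip_to_plot, compute_plot_metrics
from .modelsel import candidates_to_frame, select_and_fit
from .pointcloud import preprocess
from .synthforest import (
    SensorConfig,
    SiteData,
    StandConfig,
    miengwe_like_config,
    mwekera_like_config,
    simulate_site,
)

logger = logging.getLogger("miombo_aba")

RESPONSES = ("AGB", "BA", "DBH", "Vol")


@dataclass
class PreprocessParams:
    denoise_k: int = 10
    denoise_mult: float = 3.0
    ptin_cell: float = 20.0
    ptin_angle_deg: float = 8.0
    ptin_dist_m: float = 1.4
    ptin_close_m: float = 0.2
    dtm_cell: float = 1.0
    idw_power: float = 2.0
    idw_n: int = 12


@dataclass
class AnalysisParams:
    height_threshold: float = 2.0
    r_threshold: float = 0.85
    max_subset_size: int = 5
    cv_folds: int = 10
    relative_denominator: str = "observed"


@dataclass
class StudyResult:
    """Everything the two-site analysis produces."""

    metrics: dict[str, pd.DataFrame]  # site -> plot x metric table
    attributes: dict[str, pd.DataFrame]  # site -> plot x attribute table
    models: dict[tuple[str, str], object]  # (site|'combined', response) -> FittedModel
    candidates: dict[tuple[str, str], pd.DataFrame]
    fit_stats: pd.DataFrame  # model-fit R2/adj-R2 per site x response
    cv_stats: pd.DataFrame  # pooled-CV statistics per site x response
    transfer_stats: pd.DataFrame  # cross-site transfer statistics
    seed: int = 0


def site_metric_table(
    site: SiteData,
    pre: PreprocessParams | None = None,
    height_threshold: float = 2.0,
) -> pd.DataFrame:
    """Preprocess each plot tile, clip to the plot, and compute metrics."""
    if pre is None:
        pre = PreprocessParams()
    rows = []
    for _, p in site.plots.iterrows():
        raw = site.clouds[p["plot_id"]]
        normalized, _ = preprocess(
            raw,
            denoise_k=pre.denoise_k,
            denoise_mult=pre.denoise_mult,
            ptin_cell=pre.ptin_cell,
            ptin_angle_deg=pre.ptin_angle_deg,
            ptin_dist_m=pre.ptin_dist_m,
            ptin_close_m=pre.ptin_close_m,
            dtm_cell=pre.dtm_cell,
            idw_power=pre.idw_power,
            idw_n=pre.idw_n,
        )
        clipped = clip_to_plot(
            normalized,
            PlotDefinition(p["plot_id"], site.site, p["x"], p["y"], p["radius"]),
        )
        row = {"plot_id": p["plot_id"]}
        row.update(compute_plot_metrics(clipped, height_threshold))
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot_id")


def _usable_predictors(df: pd.DataFrame) -> pd.DataFrame:
    """Metric columns usable as regression predictors (finite everywhere)."""
    drop = {"n_points", "n_first_returns"}
    cols = [c for c in df.columns if c not in drop and df[c].notna().all()]
    return df[cols]


def analyze_study(
    metrics: dict[str, pd.DataFrame],
    attributes: dict[str, pd.DataFrame],
    params: AnalysisParams | None = None,
    allometry: AllometryParams | None = None,
    seed: int = 0,
) -> StudyResult:
    """Fit, cross-validate and transfer models for a one- or two-site study."""
    if params is None:
        params = AnalysisParams()
    sites = list(metrics.keys())
    pooled_metrics = pd.concat([metrics[s] for s in sites])
    pooled_attrs = pd.concat([attributes[s] for s in sites])
    units = dict(metrics)
    resp = dict(attributes)
    if len(sites) > 1:
        units["combined"] = pooled_metrics
        resp["combined"] = pooled_attrs

    ss = np.random.SeedSequence(seed)
    cv_seeds = {
        (unit, r): int(s.generate_state(1)[0] % (2**31))
        for (unit, r), s in zip(
            [(u, r) for u in units for r in RESPONSES],
            ss.spawn(len(units) * len(RESPONSES)),
        )
    }

    models: dict[tuple[str, str], object] = {}
    candidates: dict[tuple[str, str], pd.DataFrame] = {}
    fit_rows, cv_rows = [], []
    for unit, mtab in units.items():
        X = _usable_predictors(mtab)
        for response in RESPONSES:
            y = resp[unit].loc[X.index, response]
            model, cands, _ = select_and_fit(
                X, y, response_name=response, site=unit,
                r_threshold=params.r_threshold, max_size=params.max_subset_size,
            )
            models[(unit, response)] = model
            candidates[(unit, response)] = candidates_to_frame(cands)
            fit_rows.append(
                {"site": unit, "response": response, "n": model.n,
                 "predictors": "+".join(model.predictors),
                 "R2": model.fit_r2, "R2_adj": model.fit_adj_r2}
            )
            k = min(params.cv_folds, len(y))
            cv_res, _ = kfold_cv(
                X, y, model.predictors, k=k, seed=cv_seeds[(unit, response)],
                response_name=response,
                relative_denominator=params.relative_denominator,
            )
            cv_rows.append({"site": unit, "response": response, **cv_res.to_dict()})

    transfer_rows = []
    if len(sites) > 1:
        for target in sites:
            for source in sites:
                if source == target:
                    continue
                for response in RESPONSES:
                    model = models[(source, response)]
                    Xt = metrics[target]
                    yt = attributes[target].loc[Xt.index, response]
                    res, _ = transfer_model(
                        model, Xt, yt,
                        relative_denominator=params.relative_denominator,
                    )
                    transfer_rows.append(
                        {"site": target, "model": source, "response": response,
                         **res.to_dict()}
                    )
    else:
        logger.info("single-site study: transfer stage skipped")

    return StudyResult(
        metrics=metrics,
        attributes=attributes,
        models=models,
        candidates=candidates,
        fit_stats=pd.DataFrame(fit_rows),
        cv_stats=pd.DataFrame(cv_rows),
        transfer_stats=pd.DataFrame(transfer_rows),
        seed=seed,
    )


def run_synthetic_study(
    seed: int = 0,
    n_plots: int = 16,
    pulse_density: float = 25.0,
    plot_radius: float = 20.0,
    stand_configs: tuple[StandConfig, StandConfig] | None = None,
    sensor: SensorConfig | None = None,
    pre: PreprocessParams | None = None,
    params: AnalysisParams | None = None,
    allometry: AllometryParams | None = None,
) -> StudyResult:
    """Simulate the full two-site study and run the complete analysis.

    The default pulse density here (25 pts/m^2) is a deliberate test
    problem size; pass 300 for acquisition-density clouds.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    if stand_configs is None:
        stand_configs = (mwekera_like_config(seed=s1), miengwe_like_config(seed=s2))
    if sensor is None:
        sensor = SensorConfig(pulse_density=pulse_density)
    if allometry is None:
        allometry = AllometryParams()
    metrics: dict[str, pd.DataFrame] = {}
    attributes: dict[str, pd.DataFrame] = {}
    for cfg in stand_configs:
        logger.info("simulating site %s (%d plots, %.0f pts/m^2)",
                    cfg.site, n_plots, sensor.pulse_density)
        site = simulate_site(cfg, sensor, n_plots=n_plots, plot_radius=plot_radius)
        metrics[cfg.site] = site_metric_table(
            site, pre, (params or AnalysisParams()).height_threshold
        )
        attributes[cfg.site] = plot_attribute_table(
            site.field_trees, site.plots, allometry
        )
    return analyze_study(metrics, attributes, params, allometry, seed=seed)


def write_report(result: StudyResult, outdir) -> None:
    """Write candidate tables, model JSONs, metric/attribute tables and
    evaluation reports to ``outdir``, plus a run log with parameters."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for site, df in result.metrics.items():
        df.to_csv(out / f"metrics_{site}.csv")
    for site, df in result.attributes.items():
        df.to_csv(out / f"attributes_{site}.csv")
    for (unit, response), df in result.candidates.items():
        df.to_csv(out / f"candidates_{unit}_{response}.csv", index=False)
    for (unit, response), model in result.models.items():
        model.to_json(out / f"model_{unit}_{response}.json")
    result.fit_stats.to_csv(out / "fit_stats.csv", index=False)
    result.cv_stats.to_csv(out / "cv_stats.csv", index=False)
    if len(result.transfer_stats):
        result.transfer_stats.to_csv(out / "transfer_stats.csv", index=False)
    with open(out / "run_info.json", "w") as fh:
        json.dump({"package_version": __version__, "seed": result.seed,
                   "numpy_version": np.__version__}, fh, indent=2)
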