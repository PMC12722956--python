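"""Replication experiments: threshold recovery on the default scenarios.

Each experiment regenerates a scenario dataset, runs the tuned
random-forest protocol and the two-stage threshold analysis, and returns
the quantities the scenario plants: breakpoints, plateau levels, step
sizes, interaction-domain thresholds and variogram structure. They exist
so the same replication logic backs both the test suite and the
command-line reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ml import shap_decomposition, train_models
from .synthetic import gaussian_random_field, sample_scenario, scenario
from .thresholds import (_oof_predictions, dual_threshold_domain,
                         two_stage_thresholds)
from .variogram import Variogram


@dataclasses.dataclass
class JiaodongRun:
    seed: int
    rf_test_adj_r2: float
    no3_threshold: float | None
    no3_step: float | None
    pdp_lower_plateau: float
    pdp_upper_plateau: float
    domain_no3: float
    domain_fe: float
    domain_sign_ok: bool
    no3_deciles: np.ndarray
    fe_deciles: np.ndarray


@dataclasses.dataclass
class SouthwestRun:
    seed: int
    rf_test_adj_r2: float
    tn_threshold: float | None
    tn_step: float | None
    no3_threshold: float | None


def _fit_protocol(scn_name: str, seed: int, n_sites: int):
    cfg = scenario(scn_name, n_sites=n_sites, seed=seed)
    table, _ = sample_scenario(cfg)
    tm = train_models(table, table.covariates, split_seed=seed,
                      algorithms=("RF",))
    rf = tm.estimators["RF"]
    oof = _oof_predictions(rf, tm.X_train, tm.y_train, 10, seed)
    return tm, rf, oof


def run_jiaodong(seed: int, n_sites: int = 500) -> JiaodongRun:
    """Nitrate threshold + NO3 x Fe dual-threshold domain, one replicate."""
    tm, rf, oof = _fit_protocol("jiaodong", seed, n_sites)
    shap = shap_decomposition(rf, tm.X_train, tm.predictors,
                              interactions=True, seed=seed)
    tr = two_stage_thresholds(rf, tm.X_train, tm.predictors, "no3n",
                              shap=shap, y=tm.y_train, oof=oof, seed=seed)
    dom = dual_threshold_domain(shap, ("no3n", "fe"))
    q = np.arange(1, 10) / 10.0
    no3_dec = np.quantile(shap.X[:, tm.predictors.index("no3n")], q)
    fe_dec = np.quantile(shap.X[:, tm.predictors.index("fe")], q)
    sign_ok = (dom.sign_pattern["low1_high2"] < 0
               and dom.sign_pattern["high1_high2"] >= 0)
    return JiaodongRun(
        seed=seed,
        rf_test_adj_r2=tm.reports[0].test_adj_r2,
        no3_threshold=tr.threshold,
        no3_step=tr.fit.step_size() if tr.fit is not None else None,
        pdp_lower_plateau=tr.pdp.plateau_mean("lower"),
        pdp_upper_plateau=tr.pdp.plateau_mean("upper"),
        domain_no3=dom.thresholds[0],
        domain_fe=dom.thresholds[1],
        domain_sign_ok=sign_ok,
        no3_deciles=no3_dec,
        fe_deciles=fe_dec,
    )


def run_southwest(seed: int, n_sites: int = 500) -> SouthwestRun:
    """TN and nitrate thresholds in the continental scenario, one replicate."""
    tm, rf, oof = _fit_protocol("southwest", seed, n_sites)
    shap = shap_decomposition(rf, tm.X_train, tm.predictors,
                              interactions=False, seed=seed)
    tr_tn = two_stage_thresholds(rf, tm.X_train, tm.predictors, "tn",
                                 shap=shap, y=tm.y_train, oof=oof, seed=seed)
    tr_no3 = two_stage_thresholds(rf, tm.X_train, tm.predictors, "no3n",
                                  shap=shap, y=tm.y_train, oof=oof,
                                  seed=seed)
    return SouthwestRun(
        seed=seed,
        rf_test_adj_r2=tm.reports[0].test_adj_r2,
        tn_threshold=tr_tn.threshold,
        tn_step=tr_tn.fit.step_size() if tr_tn.fit is not None else None,
        no3_threshold=tr_no3.threshold,
    )


def variogram_recovery(seeds, n_samples: int = 400,
                       sample_seed: int = 0) -> dict:
    """Fit-and-select on point samples of range-68 spherical truth fields."""
    cfg = scenario("southwest")
    truth = cfg.field_variograms["tn"]
    xy = cfg.grid.cell_centers_flat()
    rng = np.random.default_rng(sample_seed)
    families, ranges = [], []
    for seed in seeds:
        field = gaussian_random_field(cfg.grid, truth, seed=seed)
        idx = rng.choice(cfg.grid.n_cells, n_samples, replace=False)
        fit = Variogram(xy[idx], field.values.ravel()[idx]).fit()
        families.append(fit.model.family)
        ranges.append(fit.model.range_)
    return {"families": families, "ranges": ranges,
            "median_range": float(np.median(ranges)),
            "truth_range": truth.range_}


def median(values) -> float:
    vals = [v for v in values if v is not None]
    return float(np.median(vals)) if vals else float("nan")
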