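"""ML harness: model training protocol, metrics, importance, PDP, Shapley.

Protocol: 70/30 train/test split stratified by region; z-standardisation
fitted on the training set only and applied to the linear and SVM models;
hyperparameters tuned by grid search inside 10-fold cross-validation on
the training set; reporting on the held-out test set with adjusted R^2

    adj R^2 = 1 - (1 - R^2) (n - 1) / (n - p - 1)

and RMSE.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .io import SampleTable
from .shapley import ShapDecomposition, shapley_values

ALGORITHMS = ("LR", "RF", "SVM-RBF", "XGBoost")

# small, standard grids sized for single-core desk runs
_GRIDS = {
    "LR": {},
    "RF": {"model__max_features": [1.0 / 3.0, 1.0]},
    "SVM-RBF": {"model__C": [1.0, 10.0, 100.0],
                "model__gamma": ["scale", 0.1, 0.01]},
    "XGBoost": {"model__learning_rate": [0.05, 0.1],
                "model__max_depth": [3, 5],
                "model__n_estimators": [300]},
}


def adjusted_r2(y_true, y_pred, n_predictors: int) -> float:
    n = len(y_true)
    r2 = r2_score(y_true, y_pred)
    denom = n - n_predictors - 1
    if denom <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / denom


@dataclasses.dataclass
class ModelReport:
    algorithm: str
    hyperparameters: dict
    test_adj_r2: float
    test_rmse: float
    cv_scores: np.ndarray

    def as_row(self) -> dict:
        return {"algorithm": self.algorithm,
                "test_adj_r2": self.test_adj_r2,
                "test_rmse": self.test_rmse,
                "cv_mean_r2": float(np.mean(self.cv_scores)),
                **{k.replace("model__", ""): v
                   for k, v in self.hyperparameters.items()}}


def _make_pipeline(algorithm: str, seed: int) -> Pipeline:
    if algorithm == "LR":
        steps = [("scale", StandardScaler()), ("model", LinearRegression())]
    elif algorithm == "RF":
        steps = [("model", RandomForestRegressor(
            n_estimators=200, random_state=seed, n_jobs=1))]
    elif algorithm == "SVM-RBF":
        steps = [("scale", StandardScaler()), ("model", SVR(kernel="rbf"))]
    elif algorithm == "XGBoost":
        steps = [("model", XGBRegressor(
            random_state=seed, n_jobs=1, verbosity=0,
            objective="reg:squarederror"))]
    else:
        raise ValueError(f"unknown algorithm '{algorithm}'")
    return Pipeline(steps)


@dataclasses.dataclass
class TrainedModels:
    """Results container for the training protocol."""

    reports: list[ModelReport]
    estimators: dict[str, Pipeline]
    predictors: list[str]
    target: str
    train_index: np.ndarray
    test_index: np.ndarray
    X: pd.DataFrame
    y: np.ndarray

    @property
    def X_train(self) -> np.ndarray:
        return self.X.iloc[self.train_index].to_numpy()

    @property
    def X_test(self) -> np.ndarray:
        return self.X.iloc[self.test_index].to_numpy()

    @property
    def y_train(self) -> np.ndarray:
        return self.y[self.train_index]

    @property
    def y_test(self) -> np.ndarray:
        return self.y[self.test_index]

    def best(self) -> tuple[str, Pipeline]:
        rep = max(self.reports, key=lambda r: r.test_adj_r2)
        return rep.algorithm, self.estimators[rep.algorithm]

    def summary(self) -> str:
        frame = pd.DataFrame([r.as_row() for r in self.reports])
        return ("Model comparison (70/30 split, 10-fold CV tuning)\n"
                + frame.to_string(index=False, float_format="%.4g"))


def train_models(samples: SampleTable, predictors, target: str = "soc",
                 split_seed: int = 0, algorithms=ALGORITHMS,
                 cv_folds: int = 10) -> TrainedModels:
    """Run the training protocol and report held-out performance."""
    frame = samples.frame
    predictors = list(predictors)
    if len(frame) < 50:
        raise ValueError("need >= 50 rows to run the training protocol")
    X = frame[predictors]
    y = frame[target].to_numpy()
    idx = np.arange(len(frame))
    train_idx, test_idx = train_test_split(
        idx, test_size=0.30, random_state=split_seed,
        stratify=frame["region"])
    if len(train_idx) < 10 * cv_folds:
        raise ValueError(
            f"fewer than 10 training rows per CV fold "
            f"({len(train_idx)} rows, {cv_folds} folds)")
    Xtr, ytr = X.iloc[train_idx].to_numpy(), y[train_idx]
    Xte, yte = X.iloc[test_idx].to_numpy(), y[test_idx]

    reports, estimators = [], {}
    for algo in algorithms:
        pipe = _make_pipeline(algo, seed=split_seed)
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=split_seed)
        grid = _GRIDS[algo]
        if grid:
            search = GridSearchCV(pipe, grid, cv=cv, scoring="r2", n_jobs=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                search.fit(Xtr, ytr)
            est = search.best_estimator_
            params = search.best_params_
            cv_scores = search.cv_results_["mean_test_score"]
        else:
            est = pipe.fit(Xtr, ytr)
            params = {}
            from sklearn.model_selection import cross_val_score
            cv_scores = cross_val_score(est, Xtr, ytr, cv=cv, scoring="r2")
        pred = est.predict(Xte)
        reports.append(ModelReport(
            algorithm=algo,
            hyperparameters=params,
            test_adj_r2=adjusted_r2(yte, pred, len(predictors)),
            test_rmse=float(np.sqrt(mean_squared_error(yte, pred))),
            cv_scores=np.asarray(cv_scores, dtype=float),
        ))
        estimators[algo] = est
    return TrainedModels(reports, estimators, predictors, target,
                         train_idx, test_idx, X, y)


def permutation_importance(model, X_test, y_test, feature_names,
                           seed: int = 0, n_repeats: int = 20) -> pd.DataFrame:
    """Permutation importance normalised to percentages summing to 100.

    Importance of a predictor = mean increase in test MSE over ``n_repeats``
    independent permutations of its column; negative increases are floored
    at zero before normalisation.
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if X_test.shape[1] < 2:
        raise ValueError("need >= 2 predictors")
    rng = np.random.default_rng(seed)
    base_mse = mean_squared_error(y_test, model.predict(X_test))
    raw = np.zeros(X_test.shape[1])
    for j in range(X_test.shape[1]):
        if np.ptp(X_test[:, j]) == 0:
            warnings.warn(f"predictor '{feature_names[j]}' is constant; "
                          "importance set to 0")
            continue
        inc = 0.0
        for _ in range(n_repeats):
            Xp = X_test.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            inc += mean_squared_error(y_test, model.predict(Xp)) - base_mse
        raw[j] = max(inc / n_repeats, 0.0)
    total = raw.sum()
    share = 100.0 * raw / total if total > 0 else np.zeros_like(raw)
    out = pd.DataFrame({"predictor": feature_names,
                        "mse_increase": raw,
                        "importance_pct": share})
    return out.sort_values("importance_pct", ascending=False,
                           ignore_index=True)


@dataclasses.dataclass
class PDPCurve:
    predictor: str
    grid: np.ndarray
    response: np.ndarray

    def plateau_mean(self, which: str) -> float:
        """Mean response over the bottom or top quartile of grid points."""
        k = len(self.grid) // 4
        if which == "lower":
            return float(self.response[:k].mean())
        if which == "upper":
            return float(self.response[-k:].mean())
        raise ValueError("which must be 'lower' or 'upper'")

    def plot(self, ax=None, **kwargs):
        """Line plot of the partial-dependence curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.response, **kwargs)
        ax.set_xlabel(self.predictor)
        ax.set_ylabel("partial dependence")
        return ax


def partial_dependence(model, X, feature_names, predictor: str,
                       n_grid: int = 50) -> PDPCurve:
    """PDP on a quantile-spaced grid between the 1st and 99th percentile."""
    X = np.asarray(X, dtype=float)
    j = list(feature_names).index(predictor)
    col = X[:, j]
    uniq = np.unique(col)
    if len(uniq) < n_grid:
        warnings.warn(f"predictor '{predictor}' has only {len(uniq)} "
                      "distinct values; grid reduced")
        grid = uniq
    else:
        qs = np.linspace(0.01, 0.99, n_grid)
        grid = np.unique(np.quantile(col, qs))
    resp = np.empty(len(grid))
    Xc = X.copy()
    for i, v in enumerate(grid):
        Xc[:, j] = v
        resp[i] = float(np.mean(model.predict(Xc)))
    return PDPCurve(predictor, grid, resp)


def shap_decomposition(model, X, feature_names, background=None,
                       interactions: bool = True, max_explain: int = 200,
                       max_background: int = 50,
                       seed: int = 0) -> ShapDecomposition:
    """Exact interventional Shapley decomposition for a fitted model.

    Rows to explain and the background are subsampled (seeded) when larger
    than ``max_explain`` / ``max_background`` to bound the O(2^p) batched
    prediction cost.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    expl = X
    if len(X) > max_explain:
        expl = X[rng.choice(len(X), max_explain, replace=False)]
    bg = X if background is None else np.asarray(background, dtype=float)
    if len(bg) > max_background:
        bg = bg[rng.choice(len(bg), max_background, replace=False)]
    dec = shapley_values(model.predict, expl, bg, interactions=interactions)
    dec.feature_names = list(feature_names)
    return dec
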