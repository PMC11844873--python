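"""Model selection, nested cross-validation, permutation chance levels,
post-hoc severity classification, and feature importance.

Two nested schemes are provided.  In the per-combination scheme every model
family x parcellation is evaluated separately: a 10-fold inner loop on the
training participants selects the hyperparameter set with the lowest mean
RMSE, which is refit on all training participants to predict the held-out
participant of the leave-one-out outer loop.  In the joint scheme the inner
loop searches over model family x hyperparameters x parcellation at once and
a single winner predicts the held-out participant.  R2 and RMSE are computed
on the pooled out-of-fold predictions.  Chance level is the distribution of
pooled R2 over refits with permuted targets (fixed elastic-net model, 5-fold
outer and inner loops).

Leakage contract: all preprocessing (median imputation, standardisation of
continuous columns) is fit on the training participants of each fold only,
and every random seed is derived from the master seed and fold index by a
counter-based scheme, never from the data.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, ParameterGrid
from sklearn.svm import SVR

from .cohort import FeatureMatrix, SeverityThreshold

__all__ = [
    "ModelSpec",
    "CVScheme",
    "EvaluationResult",
    "PermutationNull",
    "DEFAULT_GRIDS",
    "nested_cv_per_combo",
    "nested_cv_joint",
    "permutation_null",
    "regression_metrics",
    "classification_metrics",
    "feature_importance",
]

MODEL_FAMILIES = ("elasticnet", "linear_svm", "random_forest", "gradient_boosting")
_FAMILY_IDS = {name: i for i, name in enumerate(MODEL_FAMILIES)}

# Documented default grids, overridable per ModelSpec.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "elasticnet": {"alpha": [0.001, 0.01, 0.1, 1.0], "l1_ratio": [0.1, 0.5, 0.9]},
    "linear_svm": {"C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [30], "max_depth": [3, None]},
    "gradient_boosting": {"n_estimators": [40], "learning_rate": [0.1], "max_depth": [2, 3]},
}


@contextmanager
def _fit_context():
    """Shared estimator-fitting context: inputs are validated once at entry,
    and the deliberately loose coordinate-descent tolerance must not spam
    convergence warnings."""
    with sklearn.config_context(assume_finite=True), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


def fold_seed(master: int, *key: int) -> int:
    """Counter-based sub-seed: deterministic fan-out from a master seed."""
    ss = np.random.SeedSequence(int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ModelSpec:
    """A model family with its hyperparameter grid and seed."""

    family: str
    hyper_grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.hyper_grid is None:
            self.hyper_grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if not self.hyper_grid:
            raise ValueError("hyperparameter grid must be nonempty")

    @property
    def grid_points(self) -> list[dict]:
        return list(ParameterGrid(self.hyper_grid))

    def make_estimator(self, params: dict, seed: int):
        if self.family == "elasticnet":
            return ElasticNet(max_iter=5000, tol=1e-3, **params)
        if self.family == "linear_svm":
            return SVR(kernel="linear", **params)
        if self.family == "random_forest":
            return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
        return GradientBoostingRegressor(random_state=seed, **params)


@dataclass
class CVScheme:
    """Nested cross-validation layout."""

    mode: str = "per_combo_default"
    outer: str | int = "leave_one_out"
    inner_k: int = 10
    inner_metric: str = "rmse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("per_combo_default", "joint_paper_E1", "fixed_model_E2"):
            raise ValueError(f"unknown CV mode {self.mode!r}")
        if self.inner_k < 2:
            raise ValueError("inner_k must be >= 2")
        if self.inner_metric != "rmse":
            raise ValueError("only RMSE inner selection is supported")

    def outer_splits(self, n: int) -> list[tuple[np.ndarray, np.ndarray]]:
        if self.outer == "leave_one_out":
            idx = np.arange(n)
            return [(np.delete(idx, i), np.array([i])) for i in range(n)]
        k = int(self.outer)
        kf = KFold(n_splits=k, shuffle=True, random_state=fold_seed(self.seed, 0))
        return list(kf.split(np.arange(n)))


@dataclass
class EvaluationResult:
    """Pooled out-of-fold predictions with metrics and per-fold records."""

    y_true: pd.Series
    predictions: pd.Series
    r2: float
    rmse: float
    chosen: list[dict]
    family: str | None = None
    parcellation: str | None = None
    fold_fits: list[dict] = field(default_factory=list, repr=False)

    def classification(self, threshold: SeverityThreshold | float) -> dict[str, float]:
        thr = threshold.value if isinstance(threshold, SeverityThreshold) else float(threshold)
        return classification_metrics(self.y_true.to_numpy(), self.predictions.to_numpy(), thr)


@dataclass
class PermutationNull:
    """Distribution of pooled R2 under target permutation."""

    r2_values: np.ndarray
    n_permutations: int
    seed: int

    @property
    def mean(self) -> float:
        return float(self.r2_values.mean())

    @property
    def percentile_95(self) -> float:
        return float(np.percentile(self.r2_values, 95))


def regression_metrics(y_true, y_pred) -> tuple[float, float]:
    """Pooled R2 = 1 - SS_res/SS_tot and RMSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length 1D arrays of size >= 2")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise ValueError("metrics require finite values")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant y_true: R2 undefined")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return 1.0 - ss_res / ss_tot, rmse


def classification_metrics(y_true, y_pred_continuous, threshold: float) -> dict[str, float]:
    """Post-hoc high/low severity classification at a score threshold.

    Positives are totals >= threshold (pinned convention).  PPV, NPV,
    sensitivity and specificity come from the 2x2 table of thresholded
    predictions against thresholded truths; AUC ranks the continuous
    predictions against the thresholded truths (midrank tie handling).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred_continuous, dtype=float)
    true_pos = y_true >= threshold
    if true_pos.all() or not true_pos.any():
        raise ValueError("only one class present after thresholding y_true; AUC undefined")
    pred_pos = y_pred >= threshold
    tp = int((true_pos & pred_pos).sum())
    fp = int((~true_pos & pred_pos).sum())
    tn = int((~true_pos & ~pred_pos).sum())
    fn = int((true_pos & ~pred_pos).sum())

    def _ratio(a: int, b: int) -> float:
        return a / b if b else float("nan")

    return {
        "auc": float(roc_auc_score(true_pos, y_pred)),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
    }


def _scale_index(features: FeatureMatrix) -> np.ndarray:
    cols = list(features.df.columns)
    return np.array([cols.index(c) for c in features.scale_columns if c in cols], dtype=int)


def _fit_prep(x_train: np.ndarray, scale_idx: np.ndarray) -> dict:
    """Training-fold preprocessing state: imputation medians and scaler stats."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        medians = np.nanmedian(x_train, axis=0)
    medians = np.where(np.isnan(medians), 0.0, medians)
    filled = np.where(np.isnan(x_train), medians, x_train)
    mu = filled.mean(axis=0)[scale_idx]
    sd = filled.std(axis=0)[scale_idx]
    sd = np.where(sd == 0, 1.0, sd)
    return {"medians": medians, "scale_idx": scale_idx, "mu": mu, "sd": sd}


def _apply_prep(x: np.ndarray, prep: dict) -> np.ndarray:
    out = np.where(np.isnan(x), prep["medians"], x)
    idx = prep["scale_idx"]
    if idx.size:
        out[:, idx] = (out[:, idx] - prep["mu"]) / prep["sd"]
    return out


def _inner_fold_arrays(
    x_train: np.ndarray,
    y_train: np.ndarray,
    scale_idx: np.ndarray,
    inner_k: int,
    split_seed: int,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Preprocessed (x_fit, x_val, y_fit, y_val) arrays for each inner fold.

    Preprocessing depends only on the fold split, so it is computed once per
    outer iteration and shared across the whole hyperparameter grid.
    """
    kf = KFold(n_splits=inner_k, shuffle=True, random_state=split_seed)
    folds = []
    for tr, va in kf.split(x_train):
        prep = _fit_prep(x_train[tr], scale_idx)
        folds.append(
            (
                _apply_prep(x_train[tr], prep),
                _apply_prep(x_train[va], prep),
                y_train[tr],
                y_train[va],
            )
        )
    return folds


def _inner_rmse(model: ModelSpec, params: dict, folds: list[tuple], est_seed: int) -> float:
    """Mean RMSE over the inner folds for one hyperparameter set."""
    rmses = []
    for xt, xv, yt, yv in folds:
        est = model.make_estimator(params, est_seed)
        est.fit(xt, yt)
        pred = est.predict(xv)
        rmses.append(float(np.sqrt(np.mean((yv - pred) ** 2))))
    return float(np.mean(rmses))


def _check_inputs(features: FeatureMatrix, targets: pd.Series, scheme: CVScheme) -> pd.Series:
    targets = targets.loc[features.df.index]
    y = targets.to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")
    if np.allclose(y, y[0]):
        raise ValueError("constant targets: R2 undefined")
    if len(y) < scheme.inner_k + 1:
        raise ValueError(f"need at least inner_k + 1 = {scheme.inner_k + 1} participants")
    return targets


def nested_cv_per_combo(
    features: FeatureMatrix,
    targets: pd.Series,
    model: ModelSpec,
    scheme: CVScheme | None = None,
    keep_fits: bool = True,
) -> EvaluationResult:
    """Nested CV for a single model family on a single feature matrix."""
    scheme = scheme or CVScheme()
    targets = _check_inputs(features, targets, scheme)
    x = features.df.to_numpy(dtype=float)
    if not np.isfinite(np.nan_to_num(x)).all():
        raise ValueError("features contain non-finite values beyond NaN")
    scale_idx = _scale_index(features)
    y = targets.to_numpy(dtype=float)
    grid = model.grid_points

    preds = np.full(len(y), np.nan)
    chosen: list[dict] = []
    fold_fits: list[dict] = []
    with _fit_context():
        for fold, (train, test) in enumerate(scheme.outer_splits(len(y))):
            split_seed = fold_seed(scheme.seed, 1, fold)
            est_seed = fold_seed(scheme.seed, 2, fold, _FAMILY_IDS[model.family], model.seed)
            x_train = x[train]
            y_train = y[train]
            folds = _inner_fold_arrays(x_train, y_train, scale_idx, scheme.inner_k, split_seed)
            scores = [_inner_rmse(model, params, folds, est_seed) for params in grid]
            best = grid[int(np.argmin(scores))]
            prep = _fit_prep(x_train, scale_idx)
            est = model.make_estimator(best, est_seed)
            est.fit(_apply_prep(x_train, prep), y_train)
            preds[test] = est.predict(_apply_prep(x[test], prep))
            chosen.append(best)
            if keep_fits:
                fold_fits.append(
                    {"estimator": est, "train_index": train, "prep": prep, "family": model.family}
                )

    r2, rmse = regression_metrics(y, preds)
    return EvaluationResult(
        y_true=pd.Series(y, index=features.df.index),
        predictions=pd.Series(preds, index=features.df.index),
        r2=r2,
        rmse=rmse,
        chosen=chosen,
        family=model.family,
        fold_fits=fold_fits,
    )


def nested_cv_joint(
    features_by_parcellation: dict[str, FeatureMatrix],
    targets: pd.Series,
    models: list[ModelSpec],
    scheme: CVScheme | None = None,
    keep_fits: bool = True,
) -> EvaluationResult:
    """Nested CV searching jointly over model family x hyperparameters x
    parcellation in the inner loop; the single winner predicts the held-out
    participant."""
    scheme = scheme or CVScheme()
    if not features_by_parcellation or not models:
        raise ValueError("need at least one parcellation and one model")
    names = list(features_by_parcellation)
    first = features_by_parcellation[names[0]]
    for fm in features_by_parcellation.values():
        if not fm.df.index.equals(first.df.index):
            raise ValueError("all parcellations must cover the same participants")
    targets = _check_inputs(first, targets, scheme)
    y = targets.to_numpy(dtype=float)
    arrays = {name: fm.df.to_numpy(dtype=float) for name, fm in features_by_parcellation.items()}
    scale_idxs = {name: _scale_index(fm) for name, fm in features_by_parcellation.items()}

    preds = np.full(len(y), np.nan)
    chosen: list[dict] = []
    fold_fits: list[dict] = []
    with _fit_context():
        for fold, (train, test) in enumerate(scheme.outer_splits(len(y))):
            split_seed = fold_seed(scheme.seed, 1, fold)
            best_key: tuple | None = None
            best_score = np.inf
            for parc in names:
                folds = _inner_fold_arrays(
                    arrays[parc][train], y[train], scale_idxs[parc], scheme.inner_k, split_seed
                )
                for model in models:
                    est_seed = fold_seed(
                        scheme.seed, 2, fold, _FAMILY_IDS[model.family], model.seed
                    )
                    for params in model.grid_points:
                        score = _inner_rmse(model, params, folds, est_seed)
                        if score < best_score:
                            best_score = score
                            best_key = (parc, model, params, est_seed)
            assert best_key is not None
            parc, model, params, est_seed = best_key
            xa = arrays[parc]
            prep = _fit_prep(xa[train], scale_idxs[parc])
            est = model.make_estimator(params, est_seed)
            est.fit(_apply_prep(xa[train], prep), y[train])
            preds[test] = est.predict(_apply_prep(xa[test], prep))
            chosen.append({"parcellation": parc, "family": model.family, **params})
            if keep_fits:
                fold_fits.append(
                    {"estimator": est, "train_index": train, "prep": prep,
                     "family": model.family, "parcellation": parc}
                )

    r2, rmse = regression_metrics(y, preds)
    return EvaluationResult(
        y_true=pd.Series(y, index=first.df.index),
        predictions=pd.Series(preds, index=first.df.index),
        r2=r2,
        rmse=rmse,
        chosen=chosen,
        family="joint",
        fold_fits=fold_fits,
    )


def permutation_null(
    features: FeatureMatrix,
    targets: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
    model: ModelSpec | None = None,
) -> PermutationNull:
    """Chance-level R2 distribution: shuffle targets, rerun nested CV.

    The fixed chance model is elastic-net with the default grid, evaluated
    with 5-fold outer and 5-fold inner loops (features untouched).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if len(targets) < 10:
        raise ValueError("need at least 10 participants for a meaningful null")
    model = model or ModelSpec("elasticnet")
    r2s = np.empty(n_permutations)
    y = targets.loc[features.df.index]
    for p in range(n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3, p)))
        permuted = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        scheme = CVScheme(outer=5, inner_k=5, seed=fold_seed(seed, 4, p))
        result = nested_cv_per_combo(features, permuted, model, scheme, keep_fits=False)
        r2s[p] = result.r2
    return PermutationNull(r2s, n_permutations, seed)


def feature_importance(result: EvaluationResult, features_by_parcellation=None) -> pd.DataFrame:
    """Per-feature median importance across the outer-fold fits.

    Linear families (elastic-net, linear SVM) report signed coefficients;
    tree families report impurity importance with the sign of the univariate
    linear correlation between the (preprocessed) feature and the training
    targets.  Output is sorted by |median importance| descending.
    """
    if not result.fold_fits:
        raise ValueError("result carries no fitted models (keep_fits=False?)")
    records: dict[str, list[float]] = {}
    for fit in result.fold_fits:
        est = fit["estimator"]
        family = fit["family"]
        if family == "joint":  # pragma: no cover - fold fits store concrete families
            raise ValueError("fold fit without a concrete family")
        if isinstance(features_by_parcellation, dict):
            fm = features_by_parcellation[fit.get("parcellation")]
        else:
            fm = features_by_parcellation
        if fm is None:
            raise ValueError("feature matrix required to compute importances")
        names = fm.feature_names
        x_train = _apply_prep(
            fm.df.iloc[fit["train_index"]].to_numpy(dtype=float), fit["prep"]
        )
        y_train = result.y_true.iloc[fit["train_index"]].to_numpy()
        if family in ("elasticnet", "linear_svm"):
            coefs = np.ravel(est.coef_)
        elif family in ("random_forest", "gradient_boosting"):
            xc = x_train - x_train.mean(axis=0)
            yc = y_train - y_train.mean()
            denom = np.linalg.norm(xc, axis=0) * np.linalg.norm(yc)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.where(denom > 0, xc.T @ yc / np.where(denom > 0, denom, 1), 0.0)
            coefs = est.feature_importances_ * np.sign(corr)
        else:
            raise ValueError(f"no defined importance for family {family!r}")
        for name, value in zip(names, coefs):
            records.setdefault(name, []).append(float(value))

    rows = [
        {"feature": name, "median_importance": float(np.median(vals)), "n_folds": len(vals)}
        for name, vals in records.items()
    ]
    table = pd.DataFrame(rows)
    table["abs_importance"] = table["median_importance"].abs()
    return (
        table.sort_values(["abs_importance", "feature"], ascending=[False, True])
        .drop(columns="abs_importance")
        .reset_index(drop=True)
    )
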