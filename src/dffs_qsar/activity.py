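"""Stage-1 activity (pIC50) regression.

Four ensemble families are supported: a bagged random forest, a
gradient-boosted tree ensemble, a histogram-based gradient-boosted ensemble,
and the cascade forest. Hyperparameters are tuned by a seeded, budgeted
random search over versioned search spaces with k-fold cross-validation;
the first trial always evaluates the family's published defaults, so the
tuned cross-validated score can never be worse than the untuned one.

Evaluation metrics are the mean relative error, mean squared error, mean
absolute error and the coefficient of determination:

    MRE = (1/n) sum |y_i - yhat_i| / |y_i|
    MSE = (1/n) sum (y_i - yhat_i)^2
    MAE = (1/n) sum |y_i - yhat_i|
    R^2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2

plus the relative-error histogram (share of test compounds per relative
error band, default bands 0-5%, 5-10%, ..., 25-30%, >30%).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from lightgbm import LGBMRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from ._seeds import child_seed
from .cascade import CascadeForestRegressor
from .data_io import DescriptorMatrix, DatasetSplit

# cosmetic mismatch in the lightgbm sklearn wrapper when fitting on arrays
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names"
)

REGRESSOR_FAMILIES = (
    "bagged_forest",
    "boosted_trees",
    "hist_boosted_trees",
    "cascade_forest",
)

DEFAULT_ERROR_BINS = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, np.inf)


@dataclass
class RegressorSpec:
    """One regressor family with its hyperparameters and seed."""

    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in REGRESSOR_FAMILIES:
            raise ValueError(
                f"family must be one of {REGRESSOR_FAMILIES}, got {self.family!r}"
            )


@dataclass
class PredictionSet:
    """Paired observed/predicted activities for a set of compounds."""

    compound_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=float).ravel()
        self.y_pred = np.asarray(self.y_pred, dtype=float).ravel()
        if not (len(self.compound_ids) == self.y_true.size == self.y_pred.size):
            raise ValueError("ids, y_true and y_pred must have equal length")
        if not (np.all(np.isfinite(self.y_true)) and np.all(np.isfinite(self.y_pred))):
            raise ValueError("predictions and observations must be finite")


@dataclass
class RegressionMetrics:
    mre: float
    mse: float
    mae: float
    r2: float

    def as_dict(self) -> dict:
        return {"mre": self.mre, "mse": self.mse, "mae": self.mae, "r2": self.r2}


@dataclass
class ErrorHistogram:
    """Relative-error distribution over half-open bands [a, b)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    proportions: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        lo = self.bin_edges[:-1]
        hi = self.bin_edges[1:]
        labels = [
            f"[{a:g}, {b:g})" if np.isfinite(b) else f">= {a:g}"
            for a, b in zip(lo, hi)
        ]
        return pd.DataFrame(
            {"band": labels, "count": self.counts, "proportion": self.proportions}
        )


# ---------------------------------------------------------------------------
# model construction


def _make_model(spec: RegressorSpec):
    hp = dict(spec.hyperparams)
    if spec.family == "bagged_forest":
        return RandomForestRegressor(random_state=spec.seed, n_jobs=1, **hp)
    if spec.family == "boosted_trees":
        return XGBRegressor(random_state=spec.seed, n_jobs=1, verbosity=0, **hp)
    if spec.family == "hist_boosted_trees":
        return LGBMRegressor(
            random_state=spec.seed,
            n_jobs=1,
            verbose=-1,
            deterministic=True,
            force_row_wise=True,
            **hp,
        )
    if spec.family == "cascade_forest":
        return CascadeForestRegressor(seed=spec.seed, **hp)
    raise ValueError(spec.family)


def fit_regressor(spec: RegressorSpec, X: DescriptorMatrix | np.ndarray, y: np.ndarray):
    """Fit one regressor; deterministic under ``spec.seed`` (single-thread)."""
    values = X.values if isinstance(X, DescriptorMatrix) else np.asarray(X, float)
    y = np.asarray(y, dtype=float).ravel()
    if values.shape[0] != y.size:
        raise ValueError("X rows must align with y")
    if np.ptp(y) == 0.0:
        warnings.warn("target is constant; the fit is degenerate", stacklevel=2)
    model = _make_model(spec)
    model.fit(values, y)
    return model


def fit_cascade_forest(
    X: DescriptorMatrix | np.ndarray,
    y: np.ndarray,
    layer_spec: dict | None = None,
    max_layers: int = 10,
    early_stop_rounds: int = 1,
    seed: int = 0,
) -> CascadeForestRegressor:
    """Fit the cascade forest directly (see :mod:`dffs_qsar.cascade`)."""
    values = X.values if isinstance(X, DescriptorMatrix) else np.asarray(X, float)
    model = CascadeForestRegressor(
        max_layers=max_layers,
        early_stop_rounds=early_stop_rounds,
        seed=seed,
        **(layer_spec or {}),
    )
    return model.fit(values, np.asarray(y, dtype=float).ravel())


# ---------------------------------------------------------------------------
# hyperparameter search


def load_search_spaces() -> dict:
    """Load the versioned per-family search spaces shipped with the package."""
    text = (
        importlib.resources.files("dffs_qsar")
        .joinpath("search_spaces.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def _sample_params(space: Mapping[str, dict], rng: np.random.Generator) -> dict:
    params = {}
    for name, spec in space.items():
        kind = spec["type"]
        if kind == "int":
            params[name] = int(rng.integers(spec["low"], spec["high"] + 1))
        elif kind == "float":
            params[name] = float(rng.uniform(spec["low"], spec["high"]))
        elif kind == "logfloat":
            params[name] = float(
                np.exp(rng.uniform(np.log(spec["low"]), np.log(spec["high"])))
            )
        elif kind == "choice":
            params[name] = spec["values"][int(rng.integers(len(spec["values"])))]
        else:
            raise ValueError(f"unknown space type {kind!r} for {name!r}")
    return params


def _cv_score(
    family: str,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    metric: str,
    seed: int,
) -> float:
    cv = KFold(n_splits=folds, shuffle=True, random_state=child_seed(seed, "cv"))
    errs = []
    for i, (tr, va) in enumerate(cv.split(X)):
        spec = RegressorSpec(family, dict(params), seed=child_seed(seed, f"fold{i}"))
        model = fit_regressor(spec, X[tr], y[tr])
        pred = model.predict(X[va])
        if metric == "mse":
            errs.append(float(np.mean((y[va] - pred) ** 2)))
        elif metric == "mre":
            errs.append(float(np.mean(np.abs(y[va] - pred) / np.abs(y[va]))))
        else:
            raise ValueError(f"unknown tuning metric {metric!r}")
    return float(np.mean(errs))


def tune_hyperparameters(
    family: str,
    X: DescriptorMatrix | np.ndarray,
    y: np.ndarray,
    budget: int = 100,
    folds: int = 5,
    metric: Literal["mse", "mre"] = "mse",
    seed: int = 0,
) -> dict:
    """Budgeted random search over the family's versioned space.

    Trial 1 always evaluates the published defaults (empty override), so the
    returned cross-validated score is never worse than the untuned model's.
    Returns ``{"params", "cv_score", "default_cv_score", "history"}``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    values = X.values if isinstance(X, DescriptorMatrix) else np.asarray(X, float)
    y = np.asarray(y, dtype=float).ravel()
    space = load_search_spaces()[family]
    rng = np.random.default_rng(child_seed(seed, f"tune:{family}"))

    history: list[dict] = []
    best_params: dict = {}
    best_score = np.inf
    default_score = None
    for trial in range(budget):
        params = {} if trial == 0 else _sample_params(space, rng)
        try:
            score = _cv_score(family, params, values, y, folds, metric, seed)
        except Exception as exc:  # a pathological draw must not kill the search
            history.append({"trial": trial, "params": params, "error": str(exc)})
            continue
        history.append({"trial": trial, "params": params, "cv_score": score})
        if trial == 0:
            default_score = score
        if score < best_score:
            best_score = score
            best_params = params
    if not np.isfinite(best_score):
        raise RuntimeError("all tuning trials failed")
    return {
        "params": best_params,
        "cv_score": best_score,
        "default_cv_score": default_score,
        "metric": metric,
        "history": history,
    }


# ---------------------------------------------------------------------------
# evaluation


def evaluate_regression(p: PredictionSet, with_mre: bool = True) -> RegressionMetrics:
    """Compute MRE/MSE/MAE/R^2 exactly from the paired predictions.

    MRE divides by |y_i| and is therefore undefined when any observation is
    exactly 0; that raises rather than silently fudging the denominator
    (pIC50 values are bounded away from 0 in practice).
    """
    y, yhat = p.y_true, p.y_pred
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    resid = y - yhat
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    if with_mre:
        if np.any(y == 0.0):
            raise ValueError("MRE is undefined: an observed value is exactly 0")
        mre = float(np.mean(np.abs(resid) / np.abs(y)))
    else:
        mre = float("nan")
    return RegressionMetrics(mre=mre, mse=mse, mae=mae, r2=r2)


def relative_error_histogram(
    p: PredictionSet, bin_edges: Sequence[float] = DEFAULT_ERROR_BINS
) -> ErrorHistogram:
    """Bin per-compound relative errors |y - yhat| / |y| into [a, b) bands."""
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if np.any(p.y_true == 0.0):
        raise ValueError("relative error undefined: an observed value is 0")
    rel = np.abs(p.y_true - p.y_pred) / np.abs(p.y_true)
    idx = np.clip(np.searchsorted(edges, rel, side="right") - 1, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1)
    return ErrorHistogram(edges, counts, counts / counts.sum())


def compare_feature_sets(
    feature_sets: Mapping[str, Sequence[str]],
    X: DescriptorMatrix,
    y: np.ndarray,
    spec: RegressorSpec,
    split: DatasetSplit,
    seed: int = 0,
) -> pd.DataFrame:
    """Benchmark several named descriptor subsets under one identical model.

    Every subset is trained and evaluated with the same family,
    hyperparameters, split and seed, so metric differences are attributable
    to the feature sets alone. Returns one metric row per subset.
    """
    y = np.asarray(y, dtype=float).ravel()
    id_index = {c: i for i, c in enumerate(X.compound_ids)}
    tr = [id_index[c] for c in split.train_ids]
    te = [id_index[c] for c in split.test_ids]
    rows = []
    for name, features in feature_sets.items():
        sub = X.subset_descriptors(list(features))
        model = fit_regressor(
            RegressorSpec(spec.family, dict(spec.hyperparams), seed=seed),
            sub.values[tr],
            y[tr],
        )
        pred = model.predict(sub.values[te])
        metrics = evaluate_regression(
            PredictionSet(list(split.test_ids), y[te], pred)
        )
        rows.append({"feature_set": name, **metrics.as_dict()})
    return pd.DataFrame(rows)
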