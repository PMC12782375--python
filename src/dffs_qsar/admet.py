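"""Stage-2 ADMET classification: activity gating and stacked generalization.

A compound enters ADMET modeling only if its predicted pIC50 passes the
activity threshold (default 6, inclusive). Each of the five endpoints gets
its own stacking ensemble: a menu of heterogeneous base classifiers whose
out-of-fold positive-class probabilities form the meta-feature matrix, and a
Gaussian naive Bayes meta-learner fit on those meta-features. The
out-of-fold discipline guarantees that the meta-feature for compound i comes
from base models never trained on i. Default base menus per endpoint:

    Caco-2:  svm + boosted_trees + hist_boosted_trees
    CYP3A4:  knn + bagged_forest + boosted_trees + hist_boosted_trees
    hERG:    knn + bagged_forest + boosted_trees
    HOB:     knn + boosted_trees
    MN:      boosted_trees + hist_boosted_trees

Classification quality is summarized from confusion counts:

    Accuracy = (TP+TN)/(TP+TN+FP+FN)     Precision = TP/(TP+FP)
    Recall   = TP/(TP+FN)                F1 = harmonic mean(Prec, Rec)
    FPR      = FP/(TN+FP)

plus the area under the ROC curve, computed as the Mann-Whitney
probability that a random positive outscores a random negative (ties
counted one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._seeds import child_seed
from .data_io import ADMET_PROPERTIES, DescriptorMatrix

BASE_LEARNERS = ("svm", "knn", "bagged_forest", "boosted_trees", "hist_boosted_trees")

#: Default base-learner menu per endpoint.
DEFAULT_STACKS: dict[str, tuple[str, ...]] = {
    "Caco-2": ("svm", "boosted_trees", "hist_boosted_trees"),
    "CYP3A4": ("knn", "bagged_forest", "boosted_trees", "hist_boosted_trees"),
    "hERG": ("knn", "bagged_forest", "boosted_trees"),
    "HOB": ("knn", "boosted_trees"),
    "MN": ("boosted_trees", "hist_boosted_trees"),
}


@dataclass
class GateResult:
    """Partition of compounds by the activity threshold rule."""

    retained_ids: list[str]
    rejected_ids: list[str]
    threshold: float
    inclusive: bool
    prediction_source: Literal["out_of_fold", "refit", "true_labels"] = "out_of_fold"

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_ids)


@dataclass
class StackingConfig:
    property: str
    base_learners: tuple[str, ...] | None = None
    meta_learner: str = "gaussian_nb"
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.property not in ADMET_PROPERTIES:
            raise ValueError(f"property must be one of {ADMET_PROPERTIES}")
        if self.base_learners is None:
            self.base_learners = DEFAULT_STACKS[self.property]
        self.base_learners = tuple(self.base_learners)
        unknown = [b for b in self.base_learners if b not in BASE_LEARNERS]
        if unknown:
            raise ValueError(f"unknown base learner(s) {unknown}")
        if len(self.base_learners) < 2:
            raise ValueError("stacking needs at least 2 base learners")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.meta_learner != "gaussian_nb":
            raise ValueError("only the Gaussian naive Bayes meta-learner is supported")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    fpr: float
    auc: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "fpr": self.fpr,
            "auc": self.auc,
        }


# ---------------------------------------------------------------------------
# gating


def gate_by_activity(
    predictions: Mapping[str, float],
    threshold: float = 6.0,
    inclusive: bool = True,
    prediction_source: str = "out_of_fold",
) -> GateResult:
    """Split compounds into high/low activity by predicted pIC50."""
    retained, rejected = [], []
    for cid, pred in predictions.items():
        if not np.isfinite(pred):
            raise ValueError(f"non-finite prediction for compound {cid!r}")
        ok = pred >= threshold if inclusive else pred > threshold
        (retained if ok else rejected).append(cid)
    return GateResult(retained, rejected, threshold, inclusive, prediction_source)


# ---------------------------------------------------------------------------
# base learners


def _stratified_folds(
    y: np.ndarray, folds: int, seed: int, ids: Sequence[str] | None = None
) -> np.ndarray:
    """Stratified fold index per row.

    When compound ids are available the assignment is a function of (id,
    label, seed) only — a canonical per-class ordering by id is shuffled
    with the seeded generator and dealt round-robin — so permuting the rows
    permutes the fold assignment identically (out-of-fold meta-features are
    then row-order equivariant). Without ids, positions stand in for ids.
    """
    y = np.asarray(y).astype(int).ravel()
    keys = np.asarray(ids if ids is not None else np.arange(y.size).astype(str))
    rng = np.random.default_rng(child_seed(seed, "folds"))
    fold_of = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        rows = rows[np.argsort(keys[rows])]  # canonical order
        rows = rows[rng.permutation(rows.size)]
        fold_of[rows] = np.arange(rows.size) % folds
    return fold_of


def _make_base(name: str, seed: int):
    if name == "svm":
        # probability outputs via Platt scaling: SVM decision values mapped
        # through a cross-validated logistic (sigmoid) fit
        from sklearn.calibration import CalibratedClassifierCV

        return CalibratedClassifierCV(
            SVC(random_state=seed), method="sigmoid", ensemble=False, cv=3
        )
    if name == "knn":
        return KNeighborsClassifier()
    if name == "bagged_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if name == "boosted_trees":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    if name == "hist_boosted_trees":
        return LGBMClassifier(
            random_state=seed,
            n_jobs=1,
            verbose=-1,
            deterministic=True,
            force_row_wise=True,
        )
    raise ValueError(f"unknown base learner {name!r}")


@dataclass
class StackedModel:
    """Fitted stacking ensemble for one ADMET endpoint."""

    config: StackingConfig
    descriptor_names: list[str]
    base_models: list = field(repr=False, default_factory=list)
    meta_model: GaussianNB = field(repr=False, default=None)
    oof_meta_features: np.ndarray = field(repr=False, default=None)

    def predict_proba(self, X: DescriptorMatrix | np.ndarray) -> np.ndarray:
        values = _align_values(X, self.descriptor_names)
        meta = np.column_stack(
            [m.predict_proba(values)[:, 1] for m in self.base_models]
        )
        return self.meta_model.predict_proba(meta)[:, 1]

    def predict(self, X: DescriptorMatrix | np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def base_probas(self, X: DescriptorMatrix | np.ndarray) -> np.ndarray:
        values = _align_values(X, self.descriptor_names)
        return np.column_stack(
            [m.predict_proba(values)[:, 1] for m in self.base_models]
        )


def _align_values(X: DescriptorMatrix | np.ndarray, names: Sequence[str]) -> np.ndarray:
    if isinstance(X, DescriptorMatrix):
        return X.subset_descriptors(list(names)).values
    values = np.asarray(X, dtype=float)
    if values.shape[1] != len(names):
        raise ValueError(
            f"expected {len(names)} descriptor columns, got {values.shape[1]}"
        )
    return values


def fit_stacking(
    cfg: StackingConfig, X: DescriptorMatrix | np.ndarray, y: np.ndarray
) -> StackedModel:
    """Fit the stacking ensemble with out-of-fold meta-features.

    Stratified k-fold cross-prediction produces, for every training
    compound, one positive-class probability per base learner from models
    that never saw that compound; the Gaussian naive Bayes meta-learner is
    fit on this (n, B) matrix. Base learners are then refit on all training
    rows for inference.
    """
    names = (
        list(X.descriptor_names)
        if isinstance(X, DescriptorMatrix)
        else [f"f{j}" for j in range(np.asarray(X).shape[1])]
    )
    values = _align_values(X, names)
    y = np.asarray(y).astype(int).ravel()
    if values.shape[0] != y.size:
        raise ValueError("X rows must align with y")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present to fit a classifier")
    if counts.min() < cfg.folds:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot stratify "
            f"{cfg.folds} folds"
        )

    ids = (
        list(X.compound_ids) if isinstance(X, DescriptorMatrix) else None
    )
    keys = np.asarray(ids if ids is not None else np.arange(y.size).astype(str))
    fold_of = _stratified_folds(y, cfg.folds, cfg.seed, ids=ids)

    def _canonical(rows: np.ndarray) -> np.ndarray:
        # fit on id-sorted rows so bootstrap/optimizer row-order effects
        # cannot break the permutation equivariance of the meta-features
        return rows[np.argsort(keys[rows])]

    meta = np.empty((values.shape[0], len(cfg.base_learners)))
    for b, base_name in enumerate(cfg.base_learners):
        for f in range(cfg.folds):
            tr = _canonical(np.flatnonzero(fold_of != f))
            va = np.flatnonzero(fold_of == f)
            model = _make_base(base_name, child_seed(cfg.seed, f"{base_name}:oof{f}"))
            model.fit(values[tr], y[tr])
            meta[va, b] = model.predict_proba(values[va])[:, 1]

    order = _canonical(np.arange(y.size))
    meta_model = GaussianNB()
    meta_model.fit(meta[order], y[order])
    base_models = []
    for base_name in cfg.base_learners:
        model = _make_base(base_name, child_seed(cfg.seed, f"{base_name}:full"))
        model.fit(values[order], y[order])
        base_models.append(model)
    return StackedModel(
        config=cfg,
        descriptor_names=names,
        base_models=base_models,
        meta_model=meta_model,
        oof_meta_features=meta,
    )


def predict_stacking(model: StackedModel, X: DescriptorMatrix | np.ndarray):
    """Positive-class probabilities and 0.5-threshold labels for new rows."""
    proba = model.predict_proba(X)
    return proba, (proba >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# evaluation


def compute_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney with ties counted half)."""
    y_true = np.asarray(y_true).astype(int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if np.unique(y_true).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y_true, scores))


def evaluate_classification(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> tuple[ClassificationMetrics, ConfusionCounts]:
    """Confusion-count metrics plus AUC for one endpoint.

    Zero-denominator precision/recall/F1 are reported as 0 with a warning so
    report tables stay machine-readable.
    """
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    counts = ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )
    metrics = metrics_from_confusion(counts)
    if scores is not None:
        metrics.auc = compute_auc(y_true, scores)
    return metrics, counts


def metrics_from_confusion(c: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy/precision/recall/F1/FPR from raw confusion counts."""

    def _ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            warnings.warn(f"{what} undefined (zero denominator); reported as 0",
                          stacklevel=3)
            return 0.0
        return num / den

    accuracy = _ratio(c.tp + c.tn, c.n, "accuracy")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    fpr = _ratio(c.fp, c.tn + c.fp, "FPR")
    return ClassificationMetrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        fpr=fpr,
        auc=float("nan"),
    )


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(FPR, TPR) pairs over all score thresholds, for ROC export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(y_true).astype(int), scores)
    return np.column_stack([fpr, tpr])
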