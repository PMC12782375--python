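"""Dual-filter feature selection (DFFS).

Every descriptor is scored three ways against a target: mutual information
(a statistical filter), mean impurity decrease in a bagged-forest ensemble,
and total split gain in a gradient-boosted ensemble (two model-based
filters). Each score vector is converted to fractional ranks (1 = most
important) and the three rank vectors are fused by their arithmetic mean:

    average_rank = (rank_MI + rank_forest + rank_gain) / 3

A lower average rank means higher overall importance. Selection takes the
k descriptors with the smallest fused rank; for the five binary ADMET
endpoints the fused rank is additionally averaged across endpoints before
selection (``fusion_mode="mean_across_targets"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.feature_selection import mutual_info_classif, mutual_info_regression
from xgboost import XGBClassifier, XGBRegressor

from ._seeds import child_seed
from .data_io import DescriptorMatrix

__all__ = [
    "MIConfig",
    "FeatureRanking",
    "SelectionResult",
    "estimate_mutual_information",
    "rank_features",
    "aggregate_ranks",
    "select_features",
    "write_selection_report",
]


@dataclass
class MIConfig:
    """Mutual-information estimator settings.

    ``quantile_bins`` is the plug-in estimate on an equal-frequency binned
    joint histogram (the discrete MI formula applied to binned data);
    ``knn`` delegates to the Kraskov-style nearest-neighbour estimator.
    """

    estimator: Literal["quantile_bins", "knn"] = "quantile_bins"
    n_bins: int = 16
    n_neighbors: int = 3
    target_kind: Literal["continuous", "binary"] = "continuous"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


@dataclass
class FeatureRanking:
    """Per-method fractional ranks and their arithmetic-mean fusion."""

    descriptor_names: list[str]
    rank_mi: np.ndarray
    rank_forest: np.ndarray
    rank_gain: np.ndarray
    average_rank: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.descriptor_names)
        for name in ("rank_mi", "rank_forest", "rank_gain", "average_rank"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (p,):
                raise ValueError(f"{name} must have one entry per descriptor")
        expected = p * (p + 1) / 2.0
        for name in ("rank_mi", "rank_forest", "rank_gain"):
            total = float(getattr(self, name).sum())
            if abs(total - expected) > 1e-6 * max(expected, 1.0):
                raise ValueError(
                    f"{name} is not a fractional ranking of 1..{p} "
                    f"(sum {total} != {expected})"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "descriptor": self.descriptor_names,
                "rank_mi": self.rank_mi,
                "rank_forest": self.rank_forest,
                "rank_gain": self.rank_gain,
                "average_rank": self.average_rank,
            }
        )


@dataclass
class SelectionResult:
    """Top-k descriptor subset with the rankings that produced it."""

    selected_names: list[str]
    k: int
    per_target_rankings: dict[str, FeatureRanking]
    fusion_mode: Literal["single", "mean_across_targets"]
    final_score: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if len(self.selected_names) != self.k:
            raise ValueError("selected_names must contain exactly k descriptors")


# ---------------------------------------------------------------------------
# mutual information


def _quantile_codes(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin codes; raw categories when few distinct values."""
    distinct = np.unique(v)
    if distinct.size <= n_bins:
        return np.searchsorted(distinct, v)
    edges = np.quantile(v, np.linspace(0.0, 1.0, n_bins + 1)[1:-1])
    edges = np.unique(edges)
    return np.searchsorted(edges, v, side="right")


def estimate_mutual_information(
    x: np.ndarray, y: np.ndarray, cfg: MIConfig | None = None
) -> float:
    """Estimate I(X;Y) in nats between one descriptor and a target.

    The default plug-in estimator bins both variables into equal-frequency
    bins (binary/low-cardinality variables keep their raw categories) and
    evaluates the discrete MI sum over the joint histogram. The knn
    alternative uses the nearest-neighbour estimator. MI is nonnegative and
    zero in the population iff X and Y are independent; the plug-in estimate
    carries a small positive bias of order (bins-1)^2 / (2n).
    """
    cfg = cfg or MIConfig()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 20:
        raise ValueError("MI estimation requires at least 20 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")

    if cfg.estimator == "knn":
        if np.ptp(x) == 0.0:
            warnings.warn("constant descriptor: MI set to 0", stacklevel=2)
            return 0.0
        fn = mutual_info_classif if cfg.target_kind == "binary" else mutual_info_regression
        val = fn(
            x.reshape(-1, 1),
            y.astype(int) if cfg.target_kind == "binary" else y,
            n_neighbors=cfg.n_neighbors,
            random_state=0,
        )[0]
        return float(max(val, 0.0))

    if cfg.estimator != "quantile_bins":
        raise ValueError(f"unknown estimator {cfg.estimator!r}")
    cx = _quantile_codes(x, cfg.n_bins)
    cy = (
        y.astype(int)
        if cfg.target_kind == "binary"
        else _quantile_codes(y, cfg.n_bins)
    )
    joint = np.zeros((cx.max() + 1, cy.max() + 1))
    np.add.at(joint, (cx, cy), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


# ---------------------------------------------------------------------------
# per-method scoring and ranking


def _scores_to_ranks(scores: np.ndarray) -> np.ndarray:
    """Descending score -> ascending fractional rank (ties share the mean)."""
    return rankdata(-np.asarray(scores, dtype=float), method="average")


def _is_binary(target: np.ndarray) -> bool:
    return np.isin(np.unique(target), (0, 1)).all() and np.unique(target).size <= 2


def rank_features(
    m: DescriptorMatrix,
    target: np.ndarray,
    method: Literal["mi", "forest_impurity", "boosting_gain"],
    seed: int = 0,
    cfg: MIConfig | None = None,
) -> np.ndarray:
    """Fractional importance ranks of every descriptor for one target.

    ``mi`` scores each descriptor independently with
    :func:`estimate_mutual_information`; ``forest_impurity`` uses mean
    impurity decrease of a bagged-tree ensemble; ``boosting_gain`` uses the
    cumulative split gain of a gradient-boosted ensemble. Scorers run with
    their published default hyperparameters so selection never depends on
    downstream tuning. Descriptors an ensemble never splits on score 0 and
    therefore share the worst fractional rank.
    """
    target = np.asarray(target, dtype=float).ravel()
    if m.n_compounds != target.size:
        raise ValueError("target length must match descriptor rows")
    if m.n_descriptors < 2:
        raise ValueError("ranking requires at least 2 descriptors")
    if np.ptp(target) == 0.0:
        raise ValueError("target is constant")
    binary = _is_binary(target)

    if method == "mi":
        cfg = cfg or MIConfig(target_kind="binary" if binary else "continuous")
        scores = np.array(
            [
                estimate_mutual_information(m.values[:, j], target, cfg)
                for j in range(m.n_descriptors)
            ]
        )
    elif method == "forest_impurity":
        cls = RandomForestClassifier if binary else RandomForestRegressor
        model = cls(random_state=seed, n_jobs=1)
        model.fit(m.values, target.astype(int) if binary else target)
        scores = model.feature_importances_
    elif method == "boosting_gain":
        cls = XGBClassifier if binary else XGBRegressor
        model = cls(random_state=seed, n_jobs=1, verbosity=0)
        model.fit(m.values, target.astype(int) if binary else target)
        booster = model.get_booster()
        gain = booster.get_score(importance_type="total_gain")
        names = booster.feature_names or [f"f{j}" for j in range(m.n_descriptors)]
        scores = np.array([gain.get(name, 0.0) for name in names])
    else:
        raise ValueError(f"unknown method {method!r}")
    return _scores_to_ranks(scores)


def aggregate_ranks(
    r_mi: np.ndarray,
    r_forest: np.ndarray,
    r_gain: np.ndarray,
    descriptor_names: Sequence[str],
) -> FeatureRanking:
    """Fuse the three rank vectors by their arithmetic mean (no re-ranking)."""
    r_mi, r_forest, r_gain = (
        np.asarray(r, dtype=float) for r in (r_mi, r_forest, r_gain)
    )
    if not (r_mi.shape == r_forest.shape == r_gain.shape == (len(descriptor_names),)):
        raise ValueError("rank vectors must align over the same descriptor set")
    avg = (r_mi + r_forest + r_gain) / 3.0
    return FeatureRanking(list(descriptor_names), r_mi, r_forest, r_gain, avg)


def rank_all_methods(
    m: DescriptorMatrix,
    target: np.ndarray,
    seed: int = 0,
    mi_cfg: MIConfig | None = None,
) -> FeatureRanking:
    """Run all three filters for one target and fuse their ranks."""
    r_mi = rank_features(m, target, "mi", seed=child_seed(seed, "mi"), cfg=mi_cfg)
    r_rf = rank_features(m, target, "forest_impurity", seed=child_seed(seed, "forest"))
    r_bg = rank_features(m, target, "boosting_gain", seed=child_seed(seed, "gain"))
    return aggregate_ranks(r_mi, r_rf, r_bg, m.descriptor_names)


def top_k_by_score(
    names: Sequence[str], scores: np.ndarray, k: int
) -> list[str]:
    """Smallest-score-first top-k; exact ties break lexicographically by
    name, so selection is deterministic."""
    order = sorted(range(len(names)), key=lambda j: (scores[j], names[j]))
    return [names[j] for j in order[:k]]


def select_features(
    m: DescriptorMatrix,
    targets: np.ndarray | Mapping[str, np.ndarray],
    k: int,
    fusion_mode: Literal["single", "mean_across_targets"] | None = None,
    seed: int = 0,
    mi_cfg: MIConfig | None = None,
) -> SelectionResult:
    """Select the top-k descriptors by fused average rank.

    A single continuous target yields one :class:`FeatureRanking`; a mapping
    of five binary endpoint targets yields one ranking per endpoint whose
    average ranks are then averaged across endpoints
    (``mean_across_targets``). Ties at the selection boundary break
    lexicographically by descriptor name, making selection deterministic.
    """
    if not (0 < k <= m.n_descriptors):
        raise ValueError(f"k must be in 1..{m.n_descriptors}, got {k}")

    if isinstance(targets, Mapping):
        fusion_mode = fusion_mode or "mean_across_targets"
        rankings = {
            name: rank_all_methods(
                m, t, seed=child_seed(seed, f"target:{name}"), mi_cfg=mi_cfg
            )
            for name, t in targets.items()
        }
        stacked = np.vstack([r.average_rank for r in rankings.values()])
        if fusion_mode == "mean_across_targets":
            final = stacked.mean(axis=0)
        else:
            raise ValueError(
                "per-target selection: call select_features once per target"
            )
    else:
        fusion_mode = fusion_mode or "single"
        ranking = rank_all_methods(m, np.asarray(targets), seed=seed, mi_cfg=mi_cfg)
        rankings = {"target": ranking}
        final = ranking.average_rank

    selected = top_k_by_score(m.descriptor_names, final, k)
    return SelectionResult(
        selected_names=selected,
        k=k,
        per_target_rankings=rankings,
        fusion_mode=fusion_mode,
        final_score=pd.Series(final, index=m.descriptor_names, name="final_average_rank"),
    )


def write_selection_report(result: SelectionResult, out_dir: str | Path) -> None:
    """Write the per-descriptor rank table (CSV) and a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for target_name, ranking in result.per_target_rankings.items():
        df = ranking.to_dataframe()
        df.insert(0, "target", target_name)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table["selected"] = table["descriptor"].isin(result.selected_names)
    table.to_csv(out_dir / "selection_report.csv", index=False)
    summary = {
        "k": result.k,
        "fusion_mode": result.fusion_mode,
        "selected": result.selected_names,
    }
    import json

    (out_dir / "selection_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
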