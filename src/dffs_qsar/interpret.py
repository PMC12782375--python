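"""Model interpretation: phi-coefficient association analysis and Shapley
attributions.

The phi coefficient measures association between two binary endpoints from
their 2x2 contingency table,

    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0),

and relates exactly to the Pearson chi-square statistic (1 df, no
continuity correction) through chi2 = n * phi^2, which gives the
significance test. Shapley attributions decompose each predicted pIC50
additively over descriptors (local accuracy: attributions plus a base value
reproduce the prediction); averaging absolute attributions over compounds
yields a global importance ranking, with per-compound (value, attribution)
pairs exported for beeswarm/scatter rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from ._treeshap import ensemble_shap_values, tree_shap_values, _sklearn_tree_arrays
from .cascade import CascadeForestRegressor
from .data_io import ADMETTable, DescriptorMatrix

SIGNIFICANCE_LADDER = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class ContingencyTable2x2:
    """Observed counts n_ab = #(A=a, B=b) for two binary variables."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        """(n1., n0., n.1, n.0) — row then column sums."""
        return (
            self.n11 + self.n10,
            self.n01 + self.n00,
            self.n11 + self.n01,
            self.n10 + self.n00,
        )

    @classmethod
    def from_labels(cls, a: np.ndarray, b: np.ndarray) -> "ContingencyTable2x2":
        a = np.asarray(a).astype(int).ravel()
        b = np.asarray(b).astype(int).ravel()
        if a.size != b.size:
            raise ValueError("label vectors must have equal length")
        return cls(
            n11=int(np.sum((a == 1) & (b == 1))),
            n10=int(np.sum((a == 1) & (b == 0))),
            n01=int(np.sum((a == 0) & (b == 1))),
            n00=int(np.sum((a == 0) & (b == 0))),
        )


@dataclass
class PhiResult:
    phi: float
    chi2: float
    p_value: float
    n: int

    @property
    def stars(self) -> str:
        for cutoff, stars in SIGNIFICANCE_LADDER:
            if self.p_value < cutoff:
                return stars
        return ""


@dataclass
class PhiMatrix:
    """Symmetric endpoint-by-endpoint association matrix."""

    property_names: tuple[str, ...]
    phi: pd.DataFrame
    p_values: pd.DataFrame
    undefined: dict[str, str] = field(default_factory=dict)

    def annotated(self) -> pd.DataFrame:
        """phi values with significance stars, as the field reports them."""
        out = self.phi.copy().astype(object)
        for i, a in enumerate(self.property_names):
            for j, b in enumerate(self.property_names):
                v = self.phi.iloc[i, j]
                if np.isnan(v):
                    out.iloc[i, j] = "undefined"
                    continue
                p = self.p_values.iloc[i, j]
                stars = ""
                if i != j and not np.isnan(p):
                    for cutoff, s in SIGNIFICANCE_LADDER:
                        if p < cutoff:
                            stars = s
                            break
                out.iloc[i, j] = f"{v:.4f}{stars}"
        return out


def phi_coefficient(t: ContingencyTable2x2) -> PhiResult:
    """phi, the chi-square statistic (chi2 = n*phi^2) and its p-value."""
    n1_, n0_, n_1, n_0 = t.marginals
    if min(n1_, n0_, n_1, n_0) == 0:
        raise ValueError(
            "phi is undefined: a marginal of the 2x2 table is zero "
            f"(marginals {t.marginals})"
        )
    phi = (t.n11 * t.n00 - t.n10 * t.n01) / np.sqrt(
        float(n1_) * n0_ * n_1 * n_0
    )
    chi2 = t.n * phi**2
    p = float(chi2_dist.sf(chi2, df=1))
    return PhiResult(phi=float(phi), chi2=float(chi2), p_value=p, n=t.n)


def phi_association_matrix(labels: ADMETTable) -> PhiMatrix:
    """Pairwise phi + chi-square significance across the five endpoints.

    A constant endpoint column makes phi undefined for every pair involving
    it; those cells are NaN with the reason recorded, rather than failing
    the whole analysis.
    """
    if len(labels.compound_ids) < 2:
        raise ValueError("need at least 2 compounds")
    props = labels.property_names
    k = len(props)
    phi = np.full((k, k), np.nan)
    pvals = np.full((k, k), np.nan)
    undefined: dict[str, str] = {}
    for i, prop in enumerate(props):
        col = labels.column(prop)
        if np.ptp(col) == 0:
            undefined[prop] = (
                f"property {prop!r} is constant ({col[0]}); phi undefined"
            )
        phi[i, i] = 1.0
        pvals[i, i] = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            if props[i] in undefined or props[j] in undefined:
                continue
            res = phi_coefficient(
                ContingencyTable2x2.from_labels(
                    labels.column(props[i]), labels.column(props[j])
                )
            )
            phi[i, j] = phi[j, i] = res.phi
            pvals[i, j] = pvals[j, i] = res.p_value
    idx = list(props)
    return PhiMatrix(
        property_names=props,
        phi=pd.DataFrame(phi, index=idx, columns=idx),
        p_values=pd.DataFrame(pvals, index=idx, columns=idx),
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# Shapley attributions


@dataclass
class AttributionMatrix:
    """Per-compound, per-descriptor additive attributions (pIC50 units)."""

    compound_ids: list[str]
    descriptor_names: list[str]
    attributions: np.ndarray
    base_value: float

    def __post_init__(self) -> None:
        self.attributions = np.asarray(self.attributions, dtype=float)
        if self.attributions.shape != (
            len(self.compound_ids),
            len(self.descriptor_names),
        ):
            raise ValueError("attributions must be (n_compounds, n_descriptors)")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.attributions,
            columns=self.descriptor_names,
        )
        df.insert(0, "Name", self.compound_ids)
        return df


@dataclass
class GlobalImportance:
    """Descriptors ordered by mean |attribution|, descending."""

    descriptor_names: list[str]
    mean_abs_attribution: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "descriptor": self.descriptor_names,
                "mean_abs_attribution": self.mean_abs_attribution,
            }
        )


def _model_attributions(model, values: np.ndarray):
    """Dispatch to the exact attribution path for the model's family.

    Returns ``(phi, base, reference_prediction_or_None)``; a reference
    prediction is supplied when the model's own ``predict`` emits float32
    (the local-accuracy identity is then checked at float64 against an
    independent traversal, and the traversal against ``predict`` at float32
    precision).
    """
    from lightgbm import LGBMRegressor
    from xgboost import XGBRegressor

    if isinstance(model, LGBMRegressor):
        contrib = model.predict(values, pred_contrib=True)
        return contrib[:, :-1], float(contrib[0, -1]), None
    if isinstance(model, XGBRegressor):
        from ._treeshap import xgboost_shap_values

        return xgboost_shap_values(model.get_booster(), values, values.shape[1])
    if isinstance(model, (RandomForestRegressor, ExtraTreesRegressor)):
        phi, base = ensemble_shap_values(model.estimators_, values, values.shape[1])
        return phi, base, None
    if isinstance(model, DecisionTreeRegressor):
        phi, base = tree_shap_values(
            *_sklearn_tree_arrays(model), values, values.shape[1]
        )
        return phi, base, None
    if isinstance(model, CascadeForestRegressor):
        if model.n_layers_ != 1:
            raise TypeError(
                "attributions for cascade forests are only defined for a "
                f"single-layer cascade (got {model.n_layers_} layers); deeper "
                "cascades consume augmented features that are not descriptors"
            )
        phis, bases = zip(
            *(
                ensemble_shap_values(f.estimators_, values, values.shape[1])
                for f in model.layers_[0]
            )
        )
        return np.mean(phis, axis=0), float(np.mean(bases)), None
    raise TypeError(
        f"attributions are not defined for model type {type(model).__name__}; "
        "supported: decision-tree / forest / boosted-tree regressors"
    )


def compute_attributions(
    model,
    X: DescriptorMatrix | np.ndarray,
    compound_ids: list[str] | None = None,
    descriptor_names: list[str] | None = None,
    check_tol: float = 1e-6,
) -> AttributionMatrix:
    """Exact additive attributions for a fitted tree-ensemble regressor.

    Local accuracy — for every compound, attributions sum with the base
    value to the model prediction — is verified to ``check_tol`` regardless
    of the computation path, and a violation raises.
    """
    if isinstance(X, DescriptorMatrix):
        values = X.values
        compound_ids = compound_ids or list(X.compound_ids)
        descriptor_names = descriptor_names or list(X.descriptor_names)
    else:
        values = np.asarray(X, dtype=float)
        compound_ids = compound_ids or [f"c{i}" for i in range(values.shape[0])]
        descriptor_names = descriptor_names or [
            f"f{j}" for j in range(values.shape[1])
        ]
    phi, base, ref_pred = _model_attributions(model, values)
    pred = model.predict(values)
    if ref_pred is not None:
        # the model's own output is float32; confirm the float64 traversal
        # reproduces it to float32 precision, then check local accuracy
        # against the traversal at full precision
        drift = np.max(np.abs(ref_pred - pred) / np.maximum(1.0, np.abs(pred)))
        if drift > 1e-5:
            raise AssertionError(
                f"tree traversal disagrees with model.predict (rel {drift:g})"
            )
        pred = ref_pred
    err = np.max(np.abs(phi.sum(axis=1) + base - pred))
    if err > check_tol:
        raise AssertionError(
            f"local accuracy violated: max |sum(phi)+base-pred| = {err:g}"
        )
    return AttributionMatrix(compound_ids, descriptor_names, phi, float(base))


def global_importance(
    a: AttributionMatrix, X: DescriptorMatrix | None = None
) -> tuple[GlobalImportance, pd.DataFrame]:
    """Mean-|attribution| ranking plus the per-compound export table.

    The export table holds one row per (compound, descriptor) with the
    descriptor value (when ``X`` is given) and its attribution — the data
    behind beeswarm and dependence-scatter plots. Ties in importance keep
    input order (stable sort).
    """
    imp = np.abs(a.attributions).mean(axis=0)
    order = np.argsort(-imp, kind="stable")
    ranking = GlobalImportance(
        [a.descriptor_names[j] for j in order], imp[order]
    )
    records = []
    for j, name in enumerate(a.descriptor_names):
        values = (
            X.subset_descriptors([name]).values[:, 0]
            if X is not None
            else np.full(len(a.compound_ids), np.nan)
        )
        for i, cid in enumerate(a.compound_ids):
            records.append(
                {
                    "Name": cid,
                    "descriptor": name,
                    "value": values[i],
                    "attribution": a.attributions[i, j],
                }
            )
    return ranking, pd.DataFrame.from_records(records)


def plot_global_importance(ranking: GlobalImportance, path: str | Path, top: int = 20):
    """Horizontal bar chart of the top descriptors by mean |attribution|."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = ranking.to_dataframe().head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(df) + 1))
    ax.barh(df["descriptor"], df["mean_abs_attribution"], color="#4878d0")
    ax.set_xlabel("mean |attribution| (pIC50 units)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_beeswarm(export: pd.DataFrame, ranking: GlobalImportance,
                  path: str | Path, top: int = 10):
    """Beeswarm-style scatter: attribution spread per top descriptor,
    colored by the (rank-transformed) descriptor value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = ranking.descriptor_names[:top]
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(names) + 1))
    rng = np.random.default_rng(0)
    for row, name in enumerate(reversed(names)):
        sub = export[export["descriptor"] == name]
        colors = sub["value"].rank(pct=True).to_numpy()
        jitter = rng.uniform(-0.25, 0.25, len(sub))
        ax.scatter(sub["attribution"], row + jitter, c=colors, cmap="coolwarm",
                   s=8, alpha=0.7)
    ax.set_yticks(range(len(names)))
    ax.set_yticklabels(list(reversed(names)))
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("attribution (pIC50 units)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
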