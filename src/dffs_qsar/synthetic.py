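"""Synthetic descriptor/label generator with recorded ground truth.

The generator emulates the statistical shape of a compound-screening table:
~2,000 compounds, several hundred continuous descriptors on wildly mixed
scales including a block of constant-zero columns, a continuous pIC50
driven nonlinearly (additive + one interaction + one threshold term) by a
small informative subset plus Gaussian noise, and five binary ADMET
endpoints with planted class imbalance and pairwise association.

Endpoint labels use thresholded-Gaussian (probit) links: endpoint j fires
when a latent Gaussian score Z_j exceeds the quantile matching its target
prevalence. The scores share a single common factor with per-endpoint
loadings; the loadings are solved numerically (tetrachoric inversion of the
target phi for each pair, then a rank-one least-squares fit) so the emitted
labels hit the requested phi matrix. The common factor and each endpoint's
unique part are themselves partly descriptor-driven, so the endpoints are
learnable from descriptors while still carrying label-label association.
No chemical realism is claimed: descriptors are draws from mixed
distributions, not PaDEL output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import multivariate_normal, norm

from .data_io import (
    ADMET_PROPERTIES,
    ActivityTable,
    ADMETTable,
    DescriptorMatrix,
)

#: Default target phi matrix: the association pattern realized by common
#: factor loadings (0.65, -0.60, -0.70, 0.45, 0.10) under the default
#: prevalences — the sign/magnitude pattern of a permeability-driven
#: endpoint panel (permeability anti-associated with metabolism and cardio-
#: toxicity, positively associated with bioavailability, genotoxicity near-
#: independent).
DEFAULT_LATENT_PHI = np.array(
    [
        [1.0, -0.2268, -0.2859, 0.1484, 0.0376],
        [-0.2268, 1.0, 0.2470, -0.1321, -0.0323],
        [-0.2859, 0.2470, 1.0, -0.1608, -0.0420],
        [0.1484, -0.1321, -0.1608, 1.0, 0.0213],
        [0.0376, -0.0323, -0.0420, 0.0213, 1.0],
    ]
)


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the desk-scale benchmark."""

    n_compounds: int = 2000
    n_descriptors: int = 500
    n_informative_activity: int = 10
    n_informative_admet: int = 9
    n_constant_zero: int = 10
    noise_sd: float = 0.5  # pIC50 units, on a unit-variance signal
    pic50_sd: float = 1.3  # spread of the emitted pIC50 column
    frac_high_activity: float = 0.6236  # share of compounds with pIC50 > 6
    admet_prevalences: tuple = (0.28, 0.80, 0.65, 0.12, 0.65)
    latent_correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_LATENT_PHI.copy()
    )
    shared_signal: float = 0.95  # descriptor-driven share of the common factor
    unique_signal: float = 0.97  # descriptor-driven share of each unique part
    admet_pool_mixing: str = "dense"  # dense|sparse endpoint weights on the pool
    seed: int = 0

    def __post_init__(self) -> None:
        self.latent_correlation = np.asarray(self.latent_correlation, dtype=float)
        if self.latent_correlation.shape != (5, 5):
            raise ValueError("latent_correlation must be 5x5")
        if not np.allclose(self.latent_correlation, self.latent_correlation.T):
            raise ValueError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(self.latent_correlation), 1.0):
            raise ValueError("latent_correlation must have unit diagonal")
        if len(self.admet_prevalences) != 5 or not all(
            0 < p < 1 for p in self.admet_prevalences
        ):
            raise ValueError("admet_prevalences must be five values in (0, 1)")
        if self.n_informative_activity > self.n_descriptors:
            raise ValueError("informative count exceeds descriptor count")
        if self.n_informative_admet < 7:
            raise ValueError("n_informative_admet must be >= 7 (shared + unique blocks)")
        needed = (
            self.n_informative_activity
            + self.n_informative_admet
            + self.n_constant_zero
        )
        if needed > self.n_descriptors:
            raise ValueError(
                f"n_descriptors={self.n_descriptors} cannot hold "
                f"{needed} informative + constant columns"
            )
        if not (0 < self.shared_signal < 1 and 0 < self.unique_signal < 1):
            raise ValueError("signal shares must lie in (0, 1)")
        if self.admet_pool_mixing not in ("dense", "sparse"):
            raise ValueError("admet_pool_mixing must be dense|sparse")

    @classmethod
    def dffs_benchmark(cls, seed: int = 0) -> "SyntheticConfig":
        """Feature-selection recovery benchmark: 10 informative of 200."""
        return cls(
            n_compounds=1000,
            n_descriptors=200,
            n_informative_activity=10,
            n_informative_admet=7,
            n_constant_zero=0,
            seed=seed,
        )

    @classmethod
    def stacking_benchmark(cls, seed: int = 0) -> "SyntheticConfig":
        """Planted separable endpoint benchmark for the stacking models."""
        return cls(
            n_compounds=1000,
            n_descriptors=60,
            n_informative_activity=5,
            n_informative_admet=7,
            n_constant_zero=0,
            admet_prevalences=(0.35, 0.65, 0.55, 0.30, 0.60),
            shared_signal=0.99,
            unique_signal=0.99,
            admet_pool_mixing="sparse",
            seed=seed,
        )


@dataclass
class GroundTruth:
    """Everything planted by the generator, for assertion in tests."""

    informative_activity: list[str]
    informative_admet: dict[str, list[str]]
    activity_coefficients: dict[str, float]
    factor_loadings: np.ndarray
    thresholds: np.ndarray
    target_phi: np.ndarray
    realized_phi: np.ndarray
    realized_prevalences: np.ndarray
    frac_above_gate: float
    pic50_transform: dict[str, float]


# ---------------------------------------------------------------------------
# phi calibration


def phi_from_latent(rho: float, p_i: float, p_j: float) -> float:
    """phi of two unit Gaussians with correlation rho, each thresholded to
    hit prevalence p (label = 1 above the threshold)."""
    t_i, t_j = norm.ppf(1 - p_i), norm.ppf(1 - p_j)
    p11 = float(
        multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        ).cdf([-t_i, -t_j])
    )
    denom = np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
    return (p11 - p_i * p_j) / denom


def latent_rho_for_phi(phi_target: float, p_i: float, p_j: float,
                       pair: str = "") -> float:
    """Invert ``phi_from_latent``: the Gaussian correlation producing the
    requested phi for the given prevalences. Raises when no correlation in
    (-1, 1) can realize the target (margins bound the attainable phi)."""
    if phi_target == 0.0:
        return 0.0
    lo, hi = phi_from_latent(-0.999, p_i, p_j), phi_from_latent(0.999, p_i, p_j)
    if not (lo + 1e-9 < phi_target < hi - 1e-9):
        raise ValueError(
            f"target phi={phi_target:.4f} for pair {pair or '(i,j)'} is not "
            f"realizable with prevalences ({p_i}, {p_j}); attainable range "
            f"is [{lo:.4f}, {hi:.4f}]"
        )
    return float(
        brentq(
            lambda r: phi_from_latent(r, p_i, p_j) - phi_target,
            -0.999,
            0.999,
            xtol=1e-10,
        )
    )


def solve_factor_loadings(
    target_phi: np.ndarray, prevalences: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-endpoint loadings on one common factor matching the target phi.

    Each off-diagonal target phi is converted to the Gaussian correlation it
    requires (tetrachoric inversion), and a rank-one model lam_i * lam_j is
    fit to those correlations by least squares. Returns (loadings, required
    correlation matrix). A pair whose implied |lam_i * lam_j| cannot reach
    the required correlation leaves a documented residual; an infeasible phi
    raises inside the inversion with the offending pair named.
    """
    k = len(prevalences)
    props = ADMET_PROPERTIES
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rho[i, j] = rho[j, i] = latent_rho_for_phi(
                float(target_phi[i, j]),
                float(prevalences[i]),
                float(prevalences[j]),
                pair=f"({props[i]}, {props[j]})",
            )
    # rank-one initialization from the leading eigenpair
    w, v = np.linalg.eigh(rho)
    lam0 = np.clip(v[:, -1] * np.sqrt(max(w[-1], 1e-6)), -0.95, 0.95)
    iu = np.triu_indices(k, 1)

    def resid(lam):
        return np.outer(lam, lam)[iu] - rho[iu]

    sol = least_squares(resid, lam0, bounds=(-0.99, 0.99))
    return sol.x, rho


# ---------------------------------------------------------------------------
# generation


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[DescriptorMatrix, ActivityTable, ADMETTable, GroundTruth]:
    """Draw one dataset; bit-identical under a fixed config (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_compounds, cfg.n_descriptors
    ids = [f"CMP{i:05d}" for i in range(n)]
    names = [f"MD{j:04d}" for j in range(p)]

    n_shared = min(4, max(2, cfg.n_informative_admet - 5))
    n_pool = cfg.n_informative_admet - n_shared  # >= 5 by config validation

    # column roles, at shuffled positions
    roles = rng.permutation(p)
    act_cols = roles[: cfg.n_informative_activity]
    off = cfg.n_informative_activity
    shared_cols = roles[off : off + n_shared]
    off += n_shared
    pool_cols = roles[off : off + n_pool]
    off += n_pool
    zero_cols = roles[off : off + cfg.n_constant_zero]
    off += cfg.n_constant_zero
    noise_cols = roles[off:]

    raw = np.zeros((n, p))
    informative = np.concatenate([act_cols, shared_cols, pool_cols])
    raw[:, informative] = rng.standard_normal((n, informative.size))
    # pure-noise descriptors from mixed families/scales
    for j in noise_cols:
        family = rng.integers(4)
        if family == 0:
            raw[:, j] = rng.normal(rng.uniform(-5, 5), 10 ** rng.uniform(-1, 2), n)
        elif family == 1:
            raw[:, j] = rng.lognormal(rng.uniform(0, 2), 0.8, n)
        elif family == 2:
            raw[:, j] = rng.uniform(0, 10 ** rng.uniform(0, 2), n)
        else:
            raw[:, j] = rng.poisson(rng.uniform(1, 20), n).astype(float)

    # --- activity: additive + interaction + threshold over the subset -----
    x_act = raw[:, act_cols]
    coeffs = rng.uniform(0.7, 1.3, cfg.n_informative_activity) * rng.choice(
        [-1.0, 1.0], cfg.n_informative_activity
    )
    signal = x_act @ coeffs
    signal = signal + 0.8 * x_act[:, 0] * x_act[:, 1 % x_act.shape[1]]
    signal = signal + 0.8 * (x_act[:, 2 % x_act.shape[1]] > 0.5)
    signal = _standardize(signal)
    y0 = signal + cfg.noise_sd * rng.standard_normal(n)
    scale = cfg.pic50_sd / y0.std()
    shift = 6.0 - scale * np.quantile(y0, 1.0 - cfg.frac_high_activity)
    pic50 = scale * y0 + shift
    frac_above = float(np.mean(pic50 > 6.0))

    # --- ADMET: probit links on a calibrated one-factor structure ---------
    prevalences = np.asarray(cfg.admet_prevalences, dtype=float)
    loadings, _rho = solve_factor_loadings(cfg.latent_correlation, prevalences)
    thresholds = norm.ppf(1.0 - prevalences)
    theta = cfg.shared_signal
    gamma = cfg.unique_signal

    h = _standardize(raw[:, shared_cols] @ rng.uniform(0.6, 1.4, n_shared))
    latent = rng.standard_normal(n)
    common = theta * h + np.sqrt(1 - theta**2) * latent
    # per-endpoint signals on a descriptor pool with ORTHOGONAL weight rows,
    # so the endpoint-unique parts stay uncorrelated and the rank-one phi
    # calibration is exact. "dense" mixes every pool descriptor into every
    # endpoint (overlapping subsets, exercises multi-target rank fusion);
    # "sparse" gives each endpoint its own block (maximally learnable).
    if cfg.admet_pool_mixing == "dense":
        gauss = rng.standard_normal((n_pool, 5))
        ortho, _ = np.linalg.qr(gauss)
        pool_weights = ortho.T  # (5, n_pool), rows orthonormal
    else:
        pool_weights = np.zeros((5, n_pool))
        bounds = np.linspace(0, n_pool, 6).astype(int)
        for q in range(5):
            block = slice(bounds[q], bounds[q + 1])
            w = rng.uniform(0.6, 1.4, bounds[q + 1] - bounds[q])
            pool_weights[q, block] = w / np.linalg.norm(w)
    labels = np.zeros((n, 5), dtype=int)
    informative_admet: dict[str, list[str]] = {}
    admet_names = [names[j] for j in shared_cols] + [names[j] for j in pool_cols]
    for q, prop in enumerate(ADMET_PROPERTIES):
        u = _standardize(raw[:, pool_cols] @ pool_weights[q])
        eps = rng.standard_normal(n)
        unique_part = gamma * u + np.sqrt(1 - gamma**2) * eps
        lam = loadings[q]
        z = lam * common + np.sqrt(1 - lam**2) * unique_part
        labels[:, q] = (z > thresholds[q]).astype(int)
        informative_admet[prop] = list(admet_names)

    # --- assemble the descriptor table with mixed scales ------------------
    values = raw.copy()
    scales = 10 ** rng.uniform(-1, 2, informative.size)
    locs = rng.uniform(-5, 5, informative.size)
    values[:, informative] = raw[:, informative] * scales + locs
    values[:, zero_cols] = 0.0

    realized_phi = np.corrcoef(labels, rowvar=False) if n > 1 else np.eye(5)
    truth = GroundTruth(
        informative_activity=[names[j] for j in act_cols],
        informative_admet=informative_admet,
        activity_coefficients={
            names[j]: float(c) for j, c in zip(act_cols, coeffs)
        },
        factor_loadings=loadings,
        thresholds=thresholds,
        target_phi=cfg.latent_correlation.copy(),
        realized_phi=realized_phi,
        realized_prevalences=labels.mean(axis=0),
        frac_above_gate=frac_above,
        pic50_transform={"scale": float(scale), "shift": float(shift)},
    )
    return (
        DescriptorMatrix(ids, names, values),
        ActivityTable(ids, pic50),
        ADMETTable(ids, labels),
        truth,
    )


# ---------------------------------------------------------------------------
# fixture suite


def make_fixture_suite(out_dir: str | Path) -> dict[str, str]:
    """Write the small fixed fixtures used across the test surface.

    Emits a tiny descriptor CSV (with a constant-zero column), matching
    activity and ADMET label CSVs, a worked contingency table and a
    worked regression prediction pair, plus a manifest of SHA-256 checksums.
    Deterministic: running twice yields identical checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(
        n_compounds=30,
        n_descriptors=12,
        n_informative_activity=3,
        n_informative_admet=7,
        n_constant_zero=1,
        seed=20260101,
    )
    descriptors, activity, admet, _ = generate_dataset(cfg)

    from .data_io import write_descriptor_table

    files: dict[str, str] = {}
    write_descriptor_table(descriptors, out_dir / "descriptors.csv")
    act_df = activity.pic50
    import pandas as pd

    pd.DataFrame({"Name": activity.compound_ids, "pIC50": act_df}).to_csv(
        out_dir / "activity.csv", index=False, float_format="%.17g"
    )
    admet_df = pd.DataFrame(admet.labels, columns=list(ADMET_PROPERTIES))
    admet_df.insert(0, "Name", admet.compound_ids)
    admet_df.to_csv(out_dir / "admet.csv", index=False)
    pd.DataFrame(
        {"n11": [40], "n10": [10], "n01": [10], "n00": [40]}
    ).to_csv(out_dir / "contingency_example.csv", index=False)
    pd.DataFrame({"y_true": [2.0, 4.0], "y_pred": [1.0, 5.0]}).to_csv(
        out_dir / "regression_example.csv", index=False
    )

    for f in sorted(out_dir.glob("*.csv")):
        files[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(files, indent=2) + "\n")
    return files
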