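"""Cascade forest regressor (the deep-forest cascade, tabular variant).

Each cascade layer holds four forests — two bagged random forests and two
extremely-randomized forests. The input to layer ``l`` is the original
feature block concatenated with the four per-forest predictions of layer
``l-1``. During training those augmented features are produced out-of-fold
(k-fold cross-prediction), so a layer never sees its own forests' in-sample
fit; for inference each forest is refit on the full training block. Layer
growth stops when the held-out MSE fails to improve for
``early_stop_rounds`` consecutive layers, or at ``max_layers``. The final
prediction is the mean of the last layer's four forest outputs.

Multi-grained scanning of the original deep-forest recipe is deliberately
omitted: molecular descriptors are unordered tabular features, and sliding
windows presuppose sequential or spatial structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_predict, train_test_split

from ._seeds import child_seed


def _layer_forests(n_estimators: int, min_samples_leaf: int, seed: int):
    mk = dict(
        n_estimators=n_estimators, min_samples_leaf=min_samples_leaf, n_jobs=1
    )
    return [
        RandomForestRegressor(random_state=child_seed(seed, "rf0"), **mk),
        RandomForestRegressor(random_state=child_seed(seed, "rf1"), **mk),
        ExtraTreesRegressor(random_state=child_seed(seed, "et0"), **mk),
        ExtraTreesRegressor(random_state=child_seed(seed, "et1"), **mk),
    ]


@dataclass
class CascadeForestRegressor:
    """Layered forest ensemble with prediction-augmented features."""

    n_estimators_per_forest: int = 100
    max_layers: int = 10
    early_stop_rounds: int = 1
    min_samples_leaf: int = 1
    cv_folds: int = 3
    validation_fraction: float = 0.2
    seed: int = 0

    layers_: list = field(default_factory=list, repr=False)
    n_layers_: int = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CascadeForestRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if X.shape[0] < 50:
            raise ValueError("cascade forest needs n >= 50 for a validation fold")
        idx_tr, idx_val = train_test_split(
            np.arange(X.shape[0]),
            test_size=self.validation_fraction,
            random_state=child_seed(self.seed, "val-split"),
        )
        X_tr, y_tr = X[idx_tr], y[idx_tr]
        X_val, y_val = X[idx_val], y[idx_val]

        self.layers_ = []
        aug_tr = np.empty((X_tr.shape[0], 0))
        aug_val = np.empty((X_val.shape[0], 0))
        best_mse = np.inf
        best_depth = 0
        stall = 0
        for layer_idx in range(self.max_layers):
            seed_l = child_seed(self.seed, f"layer{layer_idx}")
            forests = _layer_forests(
                self.n_estimators_per_forest, self.min_samples_leaf, seed_l
            )
            Z_tr = np.hstack([X_tr, aug_tr])
            Z_val = np.hstack([X_val, aug_val])
            oof = np.column_stack(
                [
                    cross_val_predict(
                        f,
                        Z_tr,
                        y_tr,
                        cv=KFold(
                            self.cv_folds,
                            shuffle=True,
                            random_state=child_seed(seed_l, f"cv{i}"),
                        ),
                        n_jobs=1,
                    )
                    for i, f in enumerate(forests)
                ]
            )
            for f in forests:
                f.fit(Z_tr, y_tr)
            preds_val = np.column_stack([f.predict(Z_val) for f in forests])
            mse = float(np.mean((preds_val.mean(axis=1) - y_val) ** 2))
            self.layers_.append(forests)
            if mse < best_mse - 1e-12:
                best_mse = mse
                best_depth = layer_idx + 1
                stall = 0
            else:
                stall += 1
                if stall >= self.early_stop_rounds:
                    break
            aug_tr, aug_val = oof, preds_val

        # keep only the layers up to the best validation depth
        self.layers_ = self.layers_[: max(best_depth, 1)]
        self.n_layers_ = len(self.layers_)

        # refit every retained layer on ALL training rows for inference,
        # keeping the out-of-fold augmentation discipline between layers
        aug = np.empty((X.shape[0], 0))
        refit_layers = []
        for layer_idx in range(self.n_layers_):
            seed_l = child_seed(self.seed, f"refit{layer_idx}")
            forests = _layer_forests(
                self.n_estimators_per_forest, self.min_samples_leaf, seed_l
            )
            Z = np.hstack([X, aug])
            oof = np.column_stack(
                [
                    cross_val_predict(
                        f,
                        Z,
                        y,
                        cv=KFold(
                            self.cv_folds,
                            shuffle=True,
                            random_state=child_seed(seed_l, f"cv{i}"),
                        ),
                        n_jobs=1,
                    )
                    for i, f in enumerate(forests)
                ]
            )
            for f in forests:
                f.fit(Z, y)
            refit_layers.append(forests)
            aug = oof
        self.layers_ = refit_layers
        return self

    def _forward(self, X: np.ndarray) -> np.ndarray:
        """Per-forest predictions of the final layer for new rows."""
        aug = np.empty((X.shape[0], 0))
        preds = None
        for forests in self.layers_:
            Z = np.hstack([X, aug])
            preds = np.column_stack([f.predict(Z) for f in forests])
            aug = preds
        return preds

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.layers_:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        return self._forward(X).mean(axis=1)
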