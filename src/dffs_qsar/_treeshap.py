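"""Path-dependent Shapley attributions for decision-tree ensembles.

Implements the polynomial-time tree-Shapley recursion: paths through the
tree carry, per unique feature, the fraction of "feature absent" flow (the
cover-weighted branch proportion) and the "feature present" flow (1 on the
branch the sample takes, 0 off it), together with permutation weights that
are extended at every split and unwound when a feature repeats or when a
leaf is scored. For a single tree the attributions are exactly the Shapley
values of the cover-weighted conditional-expectation game; ensembles average
them. The attributions satisfy local accuracy by construction:

    sum_j phi_ij + base = f(x_i),   base = cover-weighted mean leaf value.

The recursion kernels are plain array code so that numba can JIT them when
available; the pure-Python path is used otherwise (correct, just slower).
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "ensemble_shap_values", "expected_leaf_value"]


# --- kernels (numba-jittable: flat arrays, no Python objects) --------------


def _unwind(feat, zero, one, w, last, i):
    one_f = one[i]
    zero_f = zero[i]
    n = w[last]
    for j in range(last - 1, -1, -1):
        if one_f != 0.0:
            tmp = w[j]
            w[j] = n * (last + 1.0) / ((j + 1.0) * one_f)
            n = tmp - w[j] * zero_f * (last - j) / (last + 1.0)
        else:
            w[j] = w[j] * (last + 1.0) / (zero_f * (last - j))
    for j in range(i, last):
        feat[j] = feat[j + 1]
        zero[j] = zero[j + 1]
        one[j] = one[j + 1]


def _unwound_sum(feat, zero, one, w, last, i):
    fc = feat.copy()
    zc = zero.copy()
    oc = one.copy()
    wc = w.copy()
    _unwind(fc, zc, oc, wc, last, i)
    total = 0.0
    for j in range(last):
        total += wc[j]
    return total


def _recurse(cl, cr, split_feat, thr, val, cover, x, phi, strict,
             node, pfeat, pzero, pone, pw, ud, pz, po, pi):
    # copy the parent path, then extend it with (pz, po, pi) at index ud
    feat = np.empty(ud + 1, np.int64)
    zero = np.empty(ud + 1, np.float64)
    one = np.empty(ud + 1, np.float64)
    w = np.empty(ud + 1, np.float64)
    for j in range(ud):
        feat[j] = pfeat[j]
        zero[j] = pzero[j]
        one[j] = pone[j]
        w[j] = pw[j]
    feat[ud] = pi
    zero[ud] = pz
    one[ud] = po
    w[ud] = 1.0 if ud == 0 else 0.0
    for i in range(ud - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1.0) / (ud + 1.0)
        w[i] = pz * w[i] * (ud - i) / (ud + 1.0)
    last = ud

    if cl[node] < 0:  # leaf
        for i in range(1, last + 1):
            total = _unwound_sum(feat, zero, one, w, last, i)
            phi[feat[i]] += total * (one[i] - zero[i]) * val[node]
    else:
        d = split_feat[node]
        goes_left = x[d] < thr[node] if strict else x[d] <= thr[node]
        if goes_left:
            hot, cold = cl[node], cr[node]
        else:
            hot, cold = cr[node], cl[node]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(1, last + 1):
            if feat[i] == d:
                k = i
                break
        if k >= 0:
            iz = zero[k]
            io = one[k]
            _unwind(feat, zero, one, w, last, k)
            last -= 1
        rh = cover[hot] / cover[node]
        rc = cover[cold] / cover[node]
        _recurse(cl, cr, split_feat, thr, val, cover, x, phi, strict,
                 hot, feat, zero, one, w, last + 1, iz * rh, io, d)
        _recurse(cl, cr, split_feat, thr, val, cover, x, phi, strict,
                 cold, feat, zero, one, w, last + 1, iz * rc, 0.0, d)


_PY_KERNELS = (_unwind, _unwound_sum, _recurse)
try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _unwind = njit(_unwind)
    _unwound_sum = njit(_unwound_sum)
    _recurse = njit(_recurse)
except Exception:  # numba absent or unable to compile
    pass


def _run_recurse(cl, cr, split_feat, thr, val, cover, x, phi, strict=False):
    global _unwind, _unwound_sum, _recurse
    empty_i = np.empty(0, np.int64)
    empty_f = np.empty(0, np.float64)
    args = (cl, cr, split_feat, thr, val, cover, x, phi, strict,
            np.int64(0), empty_i, empty_f, empty_f, empty_f,
            0, 1.0, 1.0, np.int64(-1))
    try:
        _recurse(*args)
    except Exception:
        # JIT compilation failed at first use: fall back to pure Python
        _unwind, _unwound_sum, _recurse = _PY_KERNELS
        _recurse(*args)


# --- public API ------------------------------------------------------------


def expected_leaf_value(cl, val, cover) -> float:
    """Cover-weighted mean leaf value (the tree's base/expected value)."""
    leaves = cl < 0
    return float(np.sum(val[leaves] * cover[leaves]) / np.sum(cover[leaves]))


def tree_shap_values(
    children_left: np.ndarray,
    children_right: np.ndarray,
    split_feature: np.ndarray,
    threshold: np.ndarray,
    value: np.ndarray,
    cover: np.ndarray,
    X: np.ndarray,
    n_features: int,
    strict_less: bool = False,
) -> tuple[np.ndarray, float]:
    """Shapley attributions of one tree for every row of ``X``.

    Tree arrays follow the scikit-learn layout: ``children_left[i] < 0``
    marks a leaf; a sample goes left iff ``x[feature] <= threshold``
    (``x[feature] < threshold`` with ``strict_less``, the boosted-tree
    convention). ``cover`` is the (weighted) number of training samples per
    node. Returns ``(phi, base)`` with ``phi`` of shape
    ``(n_rows, n_features)``.
    """
    cl = np.asarray(children_left, np.int64)
    cr = np.asarray(children_right, np.int64)
    sf = np.asarray(split_feature, np.int64)
    thr = np.asarray(threshold, np.float64)
    val = np.asarray(value, np.float64)
    cov = np.asarray(cover, np.float64)
    X = np.asarray(X, np.float64)
    phi = np.zeros((X.shape[0], n_features))
    for r in range(X.shape[0]):
        _run_recurse(cl, cr, sf, thr, val, cov, X[r], phi[r], strict_less)
    return phi, expected_leaf_value(cl, val, cov)


def xgboost_shap_values(booster, X: np.ndarray, n_features: int):
    """Float64 Shapley attributions for an XGBoost booster.

    The booster's trees are extracted into flat arrays and pushed through
    the same recursion as scikit-learn trees (with the boosted-tree strict
    ``<`` split rule); per-tree attributions add up, and the base value is
    the model's base score plus every tree's cover-weighted mean leaf value.
    Avoids the float32 rounding of the booster's built-in contribution
    predictor, which the local-accuracy contract cannot tolerate.

    Returns ``(phi, base, prediction)`` where ``prediction`` is the float64
    model output recomputed by direct tree traversal — an independent code
    path against which local accuracy can be checked at full precision.
    """
    import json as _json

    # the booster compares in float32 and the dumped thresholds are decimal
    # approximations: push inputs and thresholds through float32 so the
    # recursion routes every sample exactly as the booster does
    X = np.asarray(X).astype(np.float32).astype(np.float64)
    cfg = _json.loads(booster.save_config())
    base = float(cfg["learner"]["learner_model_param"]["base_score"])
    feat_names = booster.feature_names
    name_to_idx = (
        {n: i for i, n in enumerate(feat_names)} if feat_names else None
    )

    def _fidx(name: str) -> int:
        if name_to_idx is not None and name in name_to_idx:
            return name_to_idx[name]
        return int(name.lstrip("f"))

    phi = np.zeros((X.shape[0], n_features))
    pred = np.full(X.shape[0], base)
    df = booster.trees_to_dataframe()
    for _, tdf in df.groupby("Tree"):
        tdf = tdf.sort_values("Node")
        pos = {nid: i for i, nid in enumerate(tdf["ID"])}
        k = len(tdf)
        cl = np.full(k, -1, np.int64)
        cr = np.full(k, -1, np.int64)
        sf = np.zeros(k, np.int64)
        thr = np.zeros(k, np.float64)
        val = np.zeros(k, np.float64)
        cov = np.asarray(tdf["Cover"], np.float64)
        is_leaf = (tdf["Feature"] == "Leaf").to_numpy()
        val[is_leaf] = tdf["Gain"].to_numpy()[is_leaf]
        for i, (_, row) in enumerate(tdf.iterrows()):
            if is_leaf[i]:
                continue
            cl[i] = pos[row["Yes"]]
            cr[i] = pos[row["No"]]
            sf[i] = _fidx(row["Feature"])
            thr[i] = float(np.float32(row["Split"]))
        p, b = tree_shap_values(cl, cr, sf, thr, val, cov, X, n_features,
                                strict_less=True)
        phi += p
        base += b
        for r in range(X.shape[0]):
            node = 0
            while cl[node] >= 0:
                node = cl[node] if X[r, sf[node]] < thr[node] else cr[node]
            pred[r] += val[node]
    return phi, base, pred


def _sklearn_tree_arrays(tree):
    t = tree.tree_
    return (
        t.children_left,
        t.children_right,
        t.feature,
        t.threshold,
        t.value[:, 0, 0],
        t.weighted_n_node_samples,
    )


def ensemble_shap_values(estimators, X: np.ndarray, n_features: int):
    """Average tree-Shapley attributions over a forest's trees.

    The forest prediction is the mean of per-tree predictions, so the
    forest attribution (and base value) is the mean of per-tree ones.
    """
    X = np.asarray(X, np.float64)
    phi = np.zeros((X.shape[0], n_features))
    base = 0.0
    for est in estimators:
        arrays = _sklearn_tree_arrays(est)
        p, b = tree_shap_values(*arrays, X, n_features)
        phi += p
        base += b
    k = len(estimators)
    return phi / k, base / k
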