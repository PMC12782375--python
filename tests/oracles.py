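"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written as plain loops / exhaustive enumeration, on
purpose: these functions must stay independent of the code paths they
verify.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial, sqrt

import numpy as np


def loop_regression_metrics(y, yhat):
    """Elementwise-loop MRE/MSE/MAE/R^2."""
    n = len(y)
    mre = mse = mae = 0.0
    ybar = sum(y) / n
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    for yi, yh in zip(y, yhat):
        mre += abs(yi - yh) / abs(yi)
        mse += (yi - yh) ** 2
        mae += abs(yi - yh)
    r2 = 1.0 - sum((yi - yh) ** 2 for yi, yh in zip(y, yhat)) / ss_tot
    return mre / n, mse / n, mae / n, r2


def loop_classification_metrics(tp, fp, tn, fn):
    """Confusion-count metric formulas, written out one by one."""
    n = tp + fp + tn + fn
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    fpr = fp / (tn + fp) if tn + fp else 0.0
    return accuracy, precision, recall, f1, fpr


def pairwise_auc(y, scores):
    """Mann-Whitney AUC: fraction of positive/negative pairs correctly
    ordered, ties counted one half."""
    pos = [s for yi, s in zip(y, scores) if yi == 1]
    neg = [s for yi, s in zip(y, scores) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def phi_by_hand(n11, n10, n01, n00):
    """Direct transcription of the 2x2 phi formula."""
    num = n11 * n00 - n10 * n01
    den = sqrt((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
    return num / den


def tree_conditional_expectation(tree_arrays, x, known):
    """E[f(x)] with only the features in ``known`` fixed; absent features
    follow both branches weighted by training cover."""
    cl, cr, feat, thr, val, cover = tree_arrays

    def rec(node):
        if cl[node] < 0:
            return val[node]
        d = feat[node]
        if d in known:
            return rec(cl[node] if x[d] <= thr[node] else cr[node])
        return (
            cover[cl[node]] * rec(cl[node]) + cover[cr[node]] * rec(cr[node])
        ) / cover[node]

    return rec(0)


def brute_force_shapley(tree_arrays, x, n_features):
    """Exact Shapley values by enumeration over the coalition lattice."""
    phi = np.zeros(n_features)
    for j in range(n_features):
        rest = [k for k in range(n_features) if k != j]
        for r in range(n_features):
            for subset in combinations(rest, r):
                weight = (
                    factorial(len(subset))
                    * factorial(n_features - len(subset) - 1)
                    / factorial(n_features)
                )
                with_j = tree_conditional_expectation(
                    tree_arrays, x, set(subset) | {j}
                )
                without_j = tree_conditional_expectation(
                    tree_arrays, x, set(subset)
                )
                phi[j] += weight * (with_j - without_j)
    return phi
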