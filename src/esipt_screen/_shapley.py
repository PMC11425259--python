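"""Exact interventional Shapley values for sklearn decision-tree ensembles.

For a fixed explicand x and one background row z, the coalition game is
v(S) = f(h) where h takes features in S from x and the rest from z.  For a
single decision tree, a leaf is reached under S iff every feature on its
path is satisfied by the row supplying it.  Collapsing repeated splits on
one feature into an interval (lo, hi], each leaf defines three feature
groups relative to (x, z): A (only x satisfies — must be in S), B (only z
satisfies — must be outside S) and irrelevant (both satisfy); a leaf where
some feature satisfies neither side is unreachable under any coalition.

The Shapley value of such a conjunction game has a closed form: with
|A| = a, |B| = b and leaf value c,

    phi_i = c * (a-1)! b! / (a+b)!     for i in A,
    phi_i = -c * a! (b-1)! / (a+b)!    for i in B,

and 0 elsewhere.  Summing over leaves, trees and background rows gives the
exact interventional Shapley values of the ensemble with base value
mean_z f(z); additivity (base + sum phi = f(x)) holds to float precision.
Cost is O(n_eval * n_background * total path conditions) per tree, handled
by a numba kernel.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from numba import njit
from scipy.special import gammaln


def leaf_conditions(children_left, children_right, feature, threshold
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, List[int]]:
    """Flatten a sklearn tree into per-leaf interval conditions.

    Returns (leaf_start, cond_feat, cond_lo, cond_hi, leaf_node_ids):
    conditions for leaf L live in slots leaf_start[L]:leaf_start[L+1], each
    requiring lo < value <= hi on one feature (sklearn routes left when
    value <= threshold).
    """
    leaf_starts = [0]
    cond_feat: List[int] = []
    cond_lo: List[float] = []
    cond_hi: List[float] = []
    leaf_ids: List[int] = []

    stack: List[Tuple[int, dict]] = [(0, {})]
    while stack:
        node, bounds = stack.pop()
        if children_left[node] == -1:  # leaf
            for f, (lo, hi) in sorted(bounds.items()):
                cond_feat.append(f)
                cond_lo.append(lo)
                cond_hi.append(hi)
            leaf_starts.append(len(cond_feat))
            leaf_ids.append(node)
            continue
        f, t = int(feature[node]), float(threshold[node])
        lo, hi = bounds.get(f, (-np.inf, np.inf))
        left_bounds = dict(bounds)
        left_bounds[f] = (lo, min(hi, t))
        right_bounds = dict(bounds)
        right_bounds[f] = (max(lo, t), hi)
        stack.append((int(children_right[node]), right_bounds))
        stack.append((int(children_left[node]), left_bounds))

    return (
        np.asarray(leaf_starts, dtype=np.int64),
        np.asarray(cond_feat, dtype=np.int64),
        np.asarray(cond_lo, dtype=np.float64),
        np.asarray(cond_hi, dtype=np.float64),
        leaf_ids,
    )


def coalition_weights(max_k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Tables WA[a,b] = (a-1)! b! / (a+b)! and WB[a,b] = a! (b-1)! / (a+b)!."""
    a = np.arange(max_k + 1, dtype=float)[:, None]
    b = np.arange(max_k + 1, dtype=float)[None, :]
    with np.errstate(invalid="ignore"):
        wa = np.exp(gammaln(a) + gammaln(b + 1.0) - gammaln(a + b + 1.0))
        wb = np.exp(gammaln(a + 1.0) + gammaln(b) - gammaln(a + b + 1.0))
    wa[0, :] = 0.0  # undefined for a = 0: no A member to credit
    wb[:, 0] = 0.0
    return wa, wb


@njit(cache=False)
def _accumulate_tree(Xe, Z, leaf_start, cond_feat, cond_lo, cond_hi,
                     leaf_val, WA, WB, scale, phi):  # pragma: no cover - numba
    n_eval = Xe.shape[0]
    m = Z.shape[0]
    n_leaves = leaf_start.shape[0] - 1
    inv_m = scale / m
    for i in range(n_eval):
        for zi in range(m):
            for L in range(n_leaves):
                s = leaf_start[L]
                e = leaf_start[L + 1]
                a = 0
                b = 0
                dead = False
                for c in range(s, e):
                    f = cond_feat[c]
                    xo = (Xe[i, f] > cond_lo[c]) and (Xe[i, f] <= cond_hi[c])
                    zo = (Z[zi, f] > cond_lo[c]) and (Z[zi, f] <= cond_hi[c])
                    if xo and zo:
                        continue
                    elif xo:
                        a += 1
                    elif zo:
                        b += 1
                    else:
                        dead = True
                        break
                if dead or (a == 0 and b == 0):
                    continue
                v = leaf_val[L]
                wa = WA[a, b]
                wb = WB[a, b]
                for c in range(s, e):
                    f = cond_feat[c]
                    xo = (Xe[i, f] > cond_lo[c]) and (Xe[i, f] <= cond_hi[c])
                    zo = (Z[zi, f] > cond_lo[c]) and (Z[zi, f] <= cond_hi[c])
                    if xo and not zo:
                        phi[i, f] += v * wa * inv_m
                    elif zo and not xo:
                        phi[i, f] -= v * wb * inv_m


def _sklearn_trees(estimator):
    """Yield the fitted DecisionTree objects inside an sklearn model."""
    if hasattr(estimator, "estimators_"):
        return [e.tree_ for e in estimator.estimators_]
    if hasattr(estimator, "tree_"):
        return [estimator.tree_]
    raise TypeError(f"{type(estimator).__name__} is not a supported tree model")


def _leaf_output(tree, positive_index):
    """Per-node scalar output: class-1 probability or regression value."""
    value = np.asarray(tree.value, dtype=float)  # (n_nodes, n_outputs, n_cls)
    if positive_index is None:
        return value[:, 0, 0]
    dist = value[:, 0, :]
    totals = dist.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return (dist / totals)[:, positive_index]


def tree_shapley_values(estimator, X_eval: np.ndarray, background: np.ndarray,
                        positive_index=None) -> np.ndarray:
    """Exact interventional Shapley matrix (n_eval x n_features).

    ``positive_index`` selects the class column for classifiers (the output
    is then the predicted positive-class probability); None means
    regression output.  The ensemble output is the mean over trees,
    matching sklearn's predict/predict_proba.
    """
    X_eval = np.ascontiguousarray(X_eval, dtype=np.float64)
    background = np.ascontiguousarray(background, dtype=np.float64)
    trees = _sklearn_trees(estimator)
    phi = np.zeros_like(X_eval)
    scale = 1.0 / len(trees)
    for tree in trees:
        leaf_start, cond_feat, cond_lo, cond_hi, leaf_ids = leaf_conditions(
            tree.children_left, tree.children_right, tree.feature, tree.threshold
        )
        node_out = _leaf_output(tree, positive_index)
        leaf_val = np.asarray([node_out[i] for i in leaf_ids], dtype=np.float64)
        max_k = int(np.max(np.diff(leaf_start))) if len(leaf_ids) else 0
        WA, WB = coalition_weights(max(max_k, 1))
        _accumulate_tree(X_eval, background, leaf_start, cond_feat, cond_lo,
                         cond_hi, leaf_val, WA, WB, scale, phi)
    return phi


def permutation_shapley_values(
    predict, X_eval: np.ndarray, background: np.ndarray,
    seed: int = 0, n_permutations: int = 64,
) -> Tuple[np.ndarray, float]:
    """Sampling estimator for non-tree models.

    Averages marginal contributions along random feature orderings, one
    background row per permutation (cycled deterministically).  Returns
    (phi, base) with base = mean over the sampled background rows of
    f(z), so additivity base + sum phi = f(x) holds exactly for every
    sample by construction of the telescoping sums.
    """
    rng = np.random.default_rng(seed)
    X_eval = np.asarray(X_eval, dtype=float)
    background = np.asarray(background, dtype=float)
    n, d = X_eval.shape
    m = background.shape[0]
    phi = np.zeros((n, d))
    base_acc = 0.0
    for r in range(n_permutations):
        order = rng.permutation(d)
        z = background[r % m]
        # states: row 0 = all-z, row t = first t features of `order` from x
        states = np.tile(z, (n * (d + 1), 1)).reshape(n, d + 1, d)
        for t in range(1, d + 1):
            cols = order[:t]
            states[:, t, cols] = X_eval[:, cols]
        flat = states.reshape(n * (d + 1), d)
        out = np.asarray(predict(flat), dtype=float).reshape(n, d + 1)
        marginals = np.diff(out, axis=1)  # (n, d), step t adds feature order[t]
        phi[:, order] += marginals / n_permutations
        base_acc += out[0, 0] / n_permutations  # f(z), same for all samples
    return phi, float(base_acc)
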