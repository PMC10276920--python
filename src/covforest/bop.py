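"""Out-of-bag nearest-neighbour sets (BOP) and covariance estimation.

For a query point x*, each tree contributes the out-of-bag training rows
that fall in the same terminal node as x*; the union over trees is the Bag
of Observations for Prediction, BOP_oob(x*).  The conditional covariance
estimate at x* is the sample covariance of the responses of that set.

For a training row i only trees where i is itself out-of-bag contribute, so
the estimate never uses trees that saw row i during growing; by default i is
also excluded from its own neighbour set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forest import DegenerateNodeError, ForestModel, node_covariance
from ._tree import route, route_with_unseen

__all__ = [
    "CovarianceEstimate",
    "NeighborSet",
    "bop_for_new",
    "bop_for_training",
    "estimate_covariance",
    "oob_estimates",
]


@dataclass
class NeighborSet:
    """BOP of one target: member training rows and per-tree provenance."""

    target: object
    members: np.ndarray
    per_tree: dict


@dataclass
class CovarianceEstimate:
    """A q x q conditional covariance estimate with its BOP size."""

    matrix: np.ndarray
    bop_size: int
    degenerate: bool = False


def _oob_leaves(forest: ForestModel):
    """Per tree: (oob row ids, their terminal node ids). Cached on the model."""
    cache = getattr(forest, "_oob_leaf_cache", None)
    if cache is None:
        X = forest.sample.X
        cat = forest.sample.is_categorical
        cache = [
            (ob, route(tree, X[ob], cat))
            for tree, ob in zip(forest.trees, forest.oob)
        ]
        forest._oob_leaf_cache = cache
    return cache


def bop_for_new(forest: ForestModel, x_star) -> NeighborSet:
    """BOP_oob(x*) for a new observation: union over all trees of the OOB
    rows sharing x*'s terminal node."""
    Xq = forest.sample.encode_query(x_star)
    if Xq.shape[0] != 1:
        raise ValueError("bop_for_new takes a single covariate vector")
    per_tree = {}
    members: set = set()
    for b, ((ob, leaves), tree) in enumerate(zip(_oob_leaves(forest), forest.trees)):
        rows, qleaves = route_with_unseen(tree, Xq, forest.sample.is_categorical)
        contrib = ob[np.isin(leaves, qleaves)]
        if contrib.size:
            per_tree[b] = contrib
            members.update(contrib.tolist())
    return NeighborSet(
        target=np.asarray(x_star),
        members=np.array(sorted(members), dtype=np.int64),
        per_tree=per_tree,
    )


def bop_for_training(
    forest: ForestModel, i: int, exclude_self: bool = True
) -> NeighborSet:
    """BOP_oob for training row i: union over trees where i is out-of-bag of
    the OOB co-members of i's terminal node.

    Raises if i was never out-of-bag (raise ``n_trees``).
    """
    n = forest.sample.n
    if not 0 <= i < n:
        raise ValueError(f"row {i} outside training sample of size {n}")
    per_tree = {}
    members: set = set()
    ever_oob = False
    for b, (ob, leaves) in enumerate(_oob_leaves(forest)):
        pos = np.searchsorted(ob, i)
        if pos >= len(ob) or ob[pos] != i:
            continue  # i in-bag for this tree: contributes nothing
        ever_oob = True
        contrib = ob[leaves == leaves[pos]]
        if exclude_self:
            contrib = contrib[contrib != i]
        if contrib.size:
            per_tree[b] = contrib
            members.update(contrib.tolist())
    if not ever_oob:
        raise ValueError(
            f"training row {i} was in-bag in every tree; "
            "increase n_trees to guarantee out-of-bag coverage"
        )
    return NeighborSet(
        target=i,
        members=np.array(sorted(members), dtype=np.int64),
        per_tree=per_tree,
    )


def _training_comembership(
    forest: ForestModel, exclude_self: bool, multiset: bool
) -> np.ndarray:
    """n x n count (or 0/1) matrix: C[i, j] = how many trees put j in i's BOP."""
    n = forest.sample.n
    dtype = np.int32 if multiset else bool
    C = np.zeros((n, n), dtype=dtype)
    for ob, leaves in _oob_leaves(forest):
        order = np.argsort(leaves, kind="stable")
        sl = leaves[order]
        starts = np.flatnonzero(np.r_[True, sl[1:] != sl[:-1]])
        bounds = np.r_[starts, len(sl)]
        for s, e in zip(bounds[:-1], bounds[1:]):
            g = ob[order[s:e]]
            if g.size < 2:
                continue
            if multiset:
                C[np.ix_(g, g)] += 1
            else:
                C[np.ix_(g, g)] = True
    if exclude_self:
        np.fill_diagonal(C, 0)
    return C


def _weighted_cov(Y: np.ndarray, w: np.ndarray) -> np.ndarray:
    W = w.sum()
    mu = w @ Y / W
    Yc = Y - mu
    S = (Yc * w[:, None]).T @ Yc / (W - 1)
    return 0.5 * (S + S.T)


def _estimate_from_weights(forest, weights, on_degenerate):
    Y = forest.sample.Y
    q = forest.sample.q
    out = []
    for w in weights:
        size = int(np.count_nonzero(w))
        total = int(w.sum())
        if total < 2:
            if on_degenerate == "raise":
                raise DegenerateNodeError(
                    f"BOP has {total} member(s); cannot form a covariance "
                    "(pass on_degenerate='fallback' or grow more trees)"
                )
            if on_degenerate == "fallback":
                out.append(
                    CovarianceEstimate(
                        matrix=node_covariance(np.arange(forest.sample.n), Y),
                        bop_size=size,
                        degenerate=True,
                    )
                )
            else:  # "nan"
                out.append(
                    CovarianceEstimate(
                        matrix=np.full((q, q), np.nan),
                        bop_size=size,
                        degenerate=True,
                    )
                )
            continue
        rows = np.flatnonzero(w)
        if w.dtype == bool or np.all(w[rows] == 1):
            S = node_covariance(rows, Y)
        else:
            S = _weighted_cov(Y[rows], w[rows].astype(np.float64))
        out.append(CovarianceEstimate(matrix=S, bop_size=size))
    return out


def oob_estimates(
    forest: ForestModel,
    exclude_self: bool = True,
    multiset: bool = False,
    on_degenerate: str = "nan",
) -> list[CovarianceEstimate]:
    """Per-training-row OOB covariance estimates (Sigma-hat for each x_i).

    Rows whose BOP holds fewer than 2 members get a NaN matrix flagged
    degenerate by default, so callers can drop them from averages.
    """
    C = _training_comembership(forest, exclude_self, multiset)
    return _estimate_from_weights(forest, C, on_degenerate)


def estimate_covariance(
    forest: ForestModel,
    X_query=None,
    multiset: bool = False,
    on_degenerate: str = "raise",
) -> list[CovarianceEstimate]:
    """Conditional covariance estimates for query rows (or, when
    ``X_query`` is None, OOB estimates for the training rows)."""
    if X_query is None:
        return oob_estimates(
            forest, multiset=multiset, on_degenerate=on_degenerate
        )
    Xq = forest.sample.encode_query(X_query)
    n = forest.sample.n
    m = Xq.shape[0]
    dtype = np.int32 if multiset else bool
    C = np.zeros((m, n), dtype=dtype)
    cat = forest.sample.is_categorical
    for (ob, leaves), tree in zip(_oob_leaves(forest), forest.trees):
        rows, qleaves = route_with_unseen(tree, Xq, cat)
        order = np.argsort(leaves, kind="stable")
        sl = leaves[order]
        for r, lf in zip(rows, qleaves):
            s = np.searchsorted(sl, lf, side="left")
            e = np.searchsorted(sl, lf, side="right")
            if e > s:
                g = ob[order[s:e]]
                if multiset:
                    C[r, g] += 1
                else:
                    C[r, g] = True
    return _estimate_from_weights(forest, C, on_degenerate)
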