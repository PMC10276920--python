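"""Forest growing and the covariance-heterogeneity splitting rule.

The forest is unsupervised in the CART sense: trees partition the covariate
space so that the response covariance matrix differs as much as possible
between sibling nodes.  Each tree is grown on a random subsample drawn
without replacement (sampsize = floor(0.632 n) by default), so every tree
has a genuine out-of-bag complement used later for estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tree import (
    Tree,
    categorical_partition_candidates,
    grow_tree,
    numeric_cut_candidates,
)
from .params import ForestParams
from .sample import SupervisedSample

__all__ = [
    "DegenerateNodeError",
    "ForestModel",
    "SplitCandidate",
    "grow_forest",
    "node_covariance",
    "propose_splits",
    "split_score",
    "upper_tri_distance",
]


class DegenerateNodeError(ValueError):
    """A node holds too few observations for a sample covariance."""


def node_covariance(rows, Y: np.ndarray) -> np.ndarray:
    """Unbiased sample covariance of the selected response rows.

    Node-mean centered with denominator (m - 1); requires at least 2 rows.
    """
    rows = np.asarray(rows)
    if rows.dtype == bool:
        rows = np.flatnonzero(rows)
    m = len(rows)
    if m < 2:
        raise DegenerateNodeError(
            f"covariance needs at least 2 rows, got {m}"
        )
    Yn = Y[rows]
    Yc = Yn - Yn.mean(axis=0)
    S = Yc.T @ Yc / (m - 1)
    return 0.5 * (S + S.T)


def upper_tri_distance(D: np.ndarray, E: np.ndarray) -> float:
    """Euclidean distance between the upper triangles of two symmetric
    matrices, diagonal included once."""
    D = np.asarray(D, dtype=float)
    E = np.asarray(E, dtype=float)
    if D.shape != E.shape or D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"incompatible shapes {D.shape} and {E.shape}")
    iu = np.triu_indices(D.shape[0])
    diff = D[iu] - E[iu]
    return float(np.sqrt(np.dot(diff, diff)))


def split_score(left_rows, right_rows, Y: np.ndarray) -> float:
    """sqrt(nL * nR) * d(Sigma_L, Sigma_R) for a candidate split."""
    left_rows = np.asarray(left_rows)
    right_rows = np.asarray(right_rows)
    nL, nR = len(left_rows), len(right_rows)
    return float(
        np.sqrt(nL * nR)
        * upper_tri_distance(
            node_covariance(left_rows, Y), node_covariance(right_rows, Y)
        )
    )


@dataclass(frozen=True)
class SplitCandidate:
    """A proposed split: numeric threshold or categorical level subset."""

    feature: int
    threshold: float | None
    left_levels: tuple | None
    left_rows: np.ndarray
    right_rows: np.ndarray


def propose_splits(
    node_rows,
    X: np.ndarray,
    is_categorical: np.ndarray,
    rng: np.random.Generator,
    mtry: int,
    nsplit: int,
    min_child: int = 2,
) -> list[SplitCandidate]:
    """Draw the randomized candidate set evaluated at a node.

    mtry covariates are drawn without replacement; numeric covariates get up
    to ``nsplit`` random cut points (midpoints of consecutive distinct
    in-node values), categorical covariates up to ``nsplit`` random proper
    level-subset partitions.  Candidates leaving a child below ``min_child``
    are excluded; the list is empty when the node is unsplittable.
    """
    node_rows = np.asarray(node_rows, dtype=np.int64)
    p = X.shape[1]
    feats = rng.permutation(p)[:mtry]
    out: list[SplitCandidate] = []
    for j in feats:
        v = X[node_rows, j]
        if is_categorical[j]:
            cand = categorical_partition_candidates(
                v.astype(np.int64), nsplit, min_child, rng
            )
            if cand is None:
                continue
            present, masks = cand
            lvl = np.searchsorted(present, v.astype(np.int64))
            for mask in masks:
                in_left = ((mask >> lvl.astype(np.uint64)) & np.uint64(1)).astype(bool)
                in_left[lvl == len(present) - 1] = False
                nL = int(in_left.sum())
                if nL < min_child or len(v) - nL < min_child:
                    continue
                lv = tuple(
                    int(present[i])
                    for i in range(len(present) - 1)
                    if (int(mask) >> i) & 1
                )
                out.append(
                    SplitCandidate(
                        feature=int(j),
                        threshold=None,
                        left_levels=lv,
                        left_rows=node_rows[in_left],
                        right_rows=node_rows[~in_left],
                    )
                )
        else:
            cand = numeric_cut_candidates(v, nsplit, min_child, rng)
            if cand is None:
                continue
            order, ks, thresholds = cand
            for k, thr in zip(ks, thresholds):
                out.append(
                    SplitCandidate(
                        feature=int(j),
                        threshold=float(thr),
                        left_levels=None,
                        left_rows=node_rows[order[:k]],
                        right_rows=node_rows[order[k:]],
                    )
                )
    return out


@dataclass
class ForestModel:
    """A grown forest plus its per-tree in-bag/out-of-bag bookkeeping."""

    sample: SupervisedSample
    params: ForestParams
    trees: list = field(default_factory=list)
    inbag: list = field(default_factory=list)
    oob: list = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def grow_forest(sample: SupervisedSample, params: ForestParams) -> ForestModel:
    """Grow ``params.n_trees`` trees on independent subsamples.

    The master seed spawns one independent stream per tree; the stream first
    draws the tree's subsample (without replacement) and then drives its
    split randomization, so the subsample-to-tree mapping is stable across
    nodesize values (common random numbers for the tuner).
    """
    params = params.resolve(sample.n, sample.p, sample.q)
    if params.nodesize is None:
        raise ValueError("nodesize must be set (or tuned) before growing")
    ss = np.random.SeedSequence(params.seed)
    child_seeds = ss.spawn(params.n_trees)
    all_rows = np.arange(sample.n)
    trees, inbags, oobs = [], [], []
    for b in range(params.n_trees):
        rng = np.random.default_rng(child_seeds[b])
        ib = np.sort(rng.choice(sample.n, size=params.sampsize, replace=False))
        ob = np.setdiff1d(all_rows, ib, assume_unique=True)
        tree = grow_tree(
            sample.X, sample.Y, sample.is_categorical, ib, params, rng
        )
        trees.append(tree)
        inbags.append(ib)
        oobs.append(ob)
    return ForestModel(
        sample=sample, params=params, trees=trees, inbag=inbags, oob=oobs
    )
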