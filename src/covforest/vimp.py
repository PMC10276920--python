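"""Fit-the-fit variable importance.

The covariance-regression forest has no observed target, so importances are
read off a second, ordinary multivariate-response forest trained to
re-predict the estimated covariance matrices: each row's estimate is
flattened to its upper triangle and used as a q(q+1)/2-variate response.
That re-prediction forest splits with a Mahalanobis-distance rule (node
impurity measured in the metric of the inverse root-node response
covariance, so correlated and differently-scaled covariance entries are
weighted coherently), and per-covariate importances are out-of-bag
permutation importances averaged over trees and (standardized) responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from ._tree import (
    Tree,
    categorical_partition_candidates,
    numeric_cut_candidates,
    route,
)
from .sample import SupervisedSample

__all__ = ["VimpResult", "flatten_upper_tri", "unflatten_upper_tri", "compute_vimp"]


def flatten_upper_tri(S: np.ndarray) -> np.ndarray:
    """Row-major upper triangle (diagonal included) of a symmetric matrix."""
    S = np.asarray(getattr(S, "matrix", S), dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("expected a square matrix")
    iu = np.triu_indices(S.shape[0])
    return S[iu]


def unflatten_upper_tri(v: np.ndarray, q: int) -> np.ndarray:
    """Inverse of :func:`flatten_upper_tri`."""
    v = np.asarray(v, dtype=float)
    if v.shape != (q * (q + 1) // 2,):
        raise ValueError(f"expected length {q * (q + 1) // 2}, got {v.shape}")
    S = np.zeros((q, q))
    iu = np.triu_indices(q)
    S[iu] = v
    S.T[iu] = v
    return S


@dataclass
class VimpResult:
    """Raw, normalized (max = 1) and ranked importances per covariate."""

    names: list
    importance: np.ndarray
    normalized: np.ndarray
    rank: np.ndarray  # 1 = most important

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names,
                "importance": self.importance,
                "normalized": self.normalized,
                "rank": self.rank,
            }
        ).sort_values("rank", ignore_index=True)


def _mahal_metric(z: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Inverse of the root-node response covariance, regularized by adding
    eps * diag(V) (plus eps * I if some response is constant)."""
    V = np.cov(z.T, ddof=1)
    V = np.atleast_2d(V)
    d = np.diag(V).copy()
    if np.any(d <= 0) or not np.isfinite(np.linalg.cond(V)) or np.linalg.cond(V) > 1e10:
        V = V + eps * np.diag(np.where(d > 0, d, 1.0))
        if np.linalg.cond(V) > 1e12:
            V = V + eps * np.trace(V) / len(d) * np.eye(len(d))
    try:
        return np.linalg.inv(V)
    except np.linalg.LinAlgError:
        V = V + 1e-3 * np.trace(V) / len(d) * np.eye(len(d))
        return np.linalg.inv(V)


def _grow_mahal_tree(X, z, W, is_cat, inbag, mtry, nsplit, nodesize, min_child, rng):
    """CART tree maximizing the Mahalanobis impurity decrease
    |s_L|^2_W / n_L + |s_R|^2_W / n_R (parent term constant)."""
    p = X.shape[1]
    feature, threshold, left_mask = [], [], []
    lchild, rchild, members = [], [], []

    def new_node(idx):
        feature.append(-1)
        threshold.append(np.nan)
        left_mask.append(np.uint64(0))
        lchild.append(-1)
        rchild.append(-1)
        members.append(idx)
        return len(feature) - 1

    stack = [new_node(np.asarray(inbag, dtype=np.int64))]
    while stack:
        v = stack.pop()
        idx = members[v]
        m = len(idx)
        if m <= nodesize or m < 2 * min_child:
            continue
        zn = z[idx]
        feats = rng.permutation(p)[:mtry]
        best = None
        for j in feats:
            col = X[idx, j]
            if is_cat[j]:
                cand = categorical_partition_candidates(
                    col.astype(np.int64), nsplit, min_child, rng
                )
                if cand is None:
                    continue
                present, masks = cand
                L = len(present)
                lvl = np.searchsorted(present, col.astype(np.int64))
                cnt = np.bincount(lvl, minlength=L).astype(float)
                c1 = np.zeros((L, z.shape[1]))
                np.add.at(c1, lvl, zn)
                bits = (
                    masks[:, None] >> np.arange(L - 1, dtype=np.uint64)[None, :]
                ) & np.uint64(1)
                M = np.concatenate(
                    [bits.astype(float), np.zeros((len(masks), 1))], axis=1
                )
                nL = M @ cnt
                ok = (nL >= min_child) & (m - nL >= min_child)
                if not ok.any():
                    continue
                masks, M, nL = masks[ok], M[ok], nL[ok]
                SL = M @ c1
                SR = c1.sum(0)[None, :] - SL
                score = (
                    np.einsum("kt,tu,ku->k", SL, W, SL) / nL
                    + np.einsum("kt,tu,ku->k", SR, W, SR) / (m - nL)
                )
                b = int(np.argmax(score))
                local = masks[b]
                gmask = np.uint64(0)
                for i in range(L - 1):
                    if (int(local) >> i) & 1:
                        gmask |= np.uint64(1) << np.uint64(present[i])
                in_left = ((local >> lvl.astype(np.uint64)) & np.uint64(1)).astype(bool)
                in_left[lvl == L - 1] = False
                if best is None or score[b] > best[0]:
                    best = (score[b], j, np.nan, gmask, np.flatnonzero(in_left))
            else:
                cand = numeric_cut_candidates(col, nsplit, min_child, rng)
                if cand is None:
                    continue
                order, ks, thresholds = cand
                c1 = np.cumsum(zn[order], axis=0)
                SL = c1[ks - 1]
                SR = c1[-1][None, :] - SL
                nL = ks.astype(float)
                score = (
                    np.einsum("kt,tu,ku->k", SL, W, SL) / nL
                    + np.einsum("kt,tu,ku->k", SR, W, SR) / (m - nL)
                )
                b = int(np.argmax(score))
                if best is None or score[b] > best[0]:
                    best = (score[b], j, thresholds[b], None, order[: ks[b]])
        if best is None:
            continue
        _, j, thr, gmask, left_rows = best
        lmask = np.zeros(m, dtype=bool)
        lmask[left_rows] = True
        lid = new_node(idx[lmask])
        rid = new_node(idx[~lmask])
        feature[v] = j
        threshold[v] = thr
        left_mask[v] = gmask if gmask is not None else np.uint64(0)
        lchild[v] = lid
        rchild[v] = rid
        stack.extend([lid, rid])

    return Tree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=np.float64),
        left_mask=np.asarray(left_mask, dtype=np.uint64),
        left_child=np.asarray(lchild, dtype=np.int64),
        right_child=np.asarray(rchild, dtype=np.int64),
        members=members,
    )


def compute_vimp(
    sample: SupervisedSample,
    estimates,
    n_trees: int = 1000,
    mtry: int | None = None,
    nsplit: int = 10,
    nodesize: int = 5,
    seed: int | None = None,
) -> VimpResult:
    """Permutation importances from the re-prediction forest.

    ``estimates`` are the per-training-row conditional covariance estimates
    (degenerate rows are dropped together with their covariates).  Each
    response column is standardized to unit variance before errors are
    averaged, so large-variance covariance entries do not dominate.
    """
    mats = [np.asarray(getattr(e, "matrix", e), dtype=float) for e in estimates]
    if len(mats) != sample.n:
        raise ValueError("estimates must align with the sample rows")
    z_all = np.array([flatten_upper_tri(S) for S in mats])
    keep = np.isfinite(z_all).all(axis=1)
    z = z_all[keep]
    X = sample.X[keep]
    p = sample.p
    names = list(sample.x_names)
    if len(np.unique(z, axis=0)) < 2:
        warnings.warn(
            "fewer than 2 distinct covariance estimates; importances are zero",
            stacklevel=2,
        )
        zero = np.zeros(p)
        return VimpResult(
            names=names,
            importance=zero,
            normalized=zero.copy(),
            rank=np.arange(1, p + 1),
        )
    n = len(z)
    mtry = mtry if mtry is not None else ceil(p / 3)
    W = _mahal_metric(z)
    col_sd = z.std(axis=0, ddof=1)
    col_sd[col_sd == 0] = 1.0
    sampsize = max(2, int(0.632 * n))
    ss = np.random.SeedSequence(seed)
    imp = np.zeros(p)
    n_used = 0
    for child in ss.spawn(n_trees):
        rng = np.random.default_rng(child)
        ib = np.sort(rng.choice(n, size=sampsize, replace=False))
        ob = np.setdiff1d(np.arange(n), ib, assume_unique=True)
        if ob.size < 2:
            continue
        tree = _grow_mahal_tree(
            X, z, W, sample.is_categorical, ib, mtry, nsplit, nodesize, 1, rng
        )
        leaf_mean = {
            int(v): z[tree.members[v]].mean(axis=0) for v in tree.leaf_ids()
        }
        Xo = X[ob]
        zo = z[ob] / col_sd
        leaves = route(tree, Xo, sample.is_categorical)
        pred = np.array([leaf_mean[int(v)] for v in leaves]) / col_sd
        base = ((zo - pred) ** 2).mean(axis=0)  # per-response MSE
        n_used += 1
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(ob.size), j]
            leaves_p = route(tree, Xp, sample.is_categorical)
            pred_p = np.array([leaf_mean[int(v)] for v in leaves_p]) / col_sd
            perm = ((zo - pred_p) ** 2).mean(axis=0)
            imp[j] += float((perm - base).mean())
    if n_used:
        imp /= n_used
    mx = imp.max()
    normalized = imp / mx if mx > 0 else np.zeros(p)
    order = np.argsort(-imp, kind="stable")
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return VimpResult(
        names=names, importance=imp, normalized=normalized, rank=rank
    )
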