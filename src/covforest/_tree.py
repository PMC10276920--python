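"""Low-level tree growing and routing.

Trees are grown CART-style on an in-bag subsample, choosing at each node the
candidate split that maximizes sqrt(nL*nR) * d(Sigma_L, Sigma_R), where
Sigma_L/R are the unbiased sample covariance matrices of the child responses
and d is the Euclidean distance over the upper triangle (diagonal included).

All candidate covariances at a node are evaluated from prefix sums of the
responses and their pairwise products, so scoring a numeric covariate costs
O(m*q^2) for the sort/cumsum plus O(K*q^2) for K candidate cut points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Tree:
    """Array-backed decision tree.

    ``feature[v] == -1`` marks node v terminal.  For categorical splits,
    ``left_mask[v]`` is a bitmask over global level codes routed left and
    ``threshold[v]`` is NaN.  ``members[v]`` holds the in-bag row ids of
    node v (kept for every node; children partition the parent).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left_mask: np.ndarray
    left_child: np.ndarray
    right_child: np.ndarray
    members: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def leaf_ids(self) -> np.ndarray:
        return np.flatnonzero(self.feature < 0)


def _pair_products(Yn: np.ndarray, iu) -> np.ndarray:
    return Yn[:, iu[0]] * Yn[:, iu[1]]


def _candidate_scores(nL, SL1, SL2, tot1, tot2, m, iu):
    """Split scores for candidate left-node sums.

    nL : (K,) left sizes; SL1 : (K, q) left response sums;
    SL2 : (K, T) left pairwise-product sums; tot1/tot2 node totals.
    """
    nL = nL.astype(np.float64)
    nR = m - nL
    SR1 = tot1[None, :] - SL1
    SR2 = tot2[None, :] - SL2
    covL = (SL2 - SL1[:, iu[0]] * SL1[:, iu[1]] / nL[:, None]) / (
        nL[:, None] - 1.0
    )
    covR = (SR2 - SR1[:, iu[0]] * SR1[:, iu[1]] / nR[:, None]) / (
        nR[:, None] - 1.0
    )
    d2 = ((covL - covR) ** 2).sum(axis=1)
    # guard tiny negative round-off before the sqrt
    return np.sqrt(np.maximum(nL * nR * d2, 0.0))


def numeric_cut_candidates(v: np.ndarray, nsplit: int, min_child: int, rng):
    """Candidate cut positions/thresholds for a numeric in-node covariate.

    Cut points are midpoints of consecutive distinct sorted values; when more
    than ``nsplit`` are admissible, ``nsplit`` are drawn uniformly without
    replacement.  Returns (order, positions, thresholds) with positions (the
    left-child sizes in sorted order) ascending, or None if no admissible cut.
    """
    m = len(v)
    order = np.argsort(v, kind="stable")
    vs = v[order]
    ks = np.flatnonzero(vs[1:] > vs[:-1]) + 1  # left size k => cut before vs[k]
    ks = ks[(ks >= min_child) & (m - ks >= min_child)]
    if ks.size == 0:
        return None
    if ks.size > nsplit:
        ks = np.sort(rng.choice(ks, size=nsplit, replace=False))
    thresholds = 0.5 * (vs[ks - 1] + vs[ks])
    return order, ks, thresholds


def categorical_partition_candidates(
    codes: np.ndarray, nsplit: int, min_child: int, rng
):
    """Candidate level-subset partitions for a categorical in-node covariate.

    Partitions are canonicalized by always keeping the largest present level
    on the right, so each of the 2^(L-1) - 1 proper partitions appears once.
    Returns (present_levels, local_masks) where bit i of a local mask selects
    ``present_levels[i]`` for the left child, or None if fewer than 2 levels.
    Child-size admissibility is checked by the caller (it needs the counts).
    """
    present = np.unique(codes)
    L = len(present)
    if L < 2:
        return None
    n_part = (1 << (L - 1)) - 1
    if n_part <= nsplit:
        masks = np.arange(1, n_part + 1, dtype=np.uint64)
    else:
        masks = (
            rng.choice(n_part, size=nsplit, replace=False).astype(np.uint64) + 1
        )
        masks.sort()
    return present, masks


def _score_numeric(Yn, P, v, nsplit, min_child, rng, iu):
    cand = numeric_cut_candidates(v, nsplit, min_child, rng)
    if cand is None:
        return None
    order, ks, thresholds = cand
    c1 = np.cumsum(Yn[order], axis=0)
    c2 = np.cumsum(P[order], axis=0)
    m = len(v)
    scores = _candidate_scores(
        ks, c1[ks - 1], c2[ks - 1], c1[-1], c2[-1], m, iu
    )
    b = int(np.argmax(scores))  # ties: smallest threshold wins
    left_rows = order[: ks[b]]
    return scores[b], thresholds[b], None, left_rows


def _score_categorical(Yn, P, v, nsplit, min_child, rng, iu):
    codes = v.astype(np.int64)
    cand = categorical_partition_candidates(codes, nsplit, min_child, rng)
    if cand is None:
        return None
    present, masks = cand
    L = len(present)
    lvl = np.searchsorted(present, codes)
    cnt = np.bincount(lvl, minlength=L).astype(np.float64)
    c1 = np.zeros((L, Yn.shape[1]))
    np.add.at(c1, lvl, Yn)
    c2 = np.zeros((L, P.shape[1]))
    np.add.at(c2, lvl, P)
    # membership matrix over the first L-1 present levels
    bits = (masks[:, None] >> np.arange(L - 1, dtype=np.uint64)[None, :]) & np.uint64(1)
    M = np.concatenate(
        [bits.astype(np.float64), np.zeros((len(masks), 1))], axis=1
    )
    nL = M @ cnt
    m = len(codes)
    ok = (nL >= min_child) & (m - nL >= min_child)
    if not ok.any():
        return None
    masks, M, nL = masks[ok], M[ok], nL[ok]
    scores = _candidate_scores(nL, M @ c1, M @ c2, c1.sum(0), c2.sum(0), m, iu)
    b = int(np.argmax(scores))
    # translate the local mask into a bitmask over global level codes
    local = masks[b]
    gmask = np.uint64(0)
    for i in range(L - 1):
        if (local >> np.uint64(i)) & np.uint64(1):
            gmask |= np.uint64(1) << np.uint64(present[i])
    in_left = (local >> lvl.astype(np.uint64)) & np.uint64(1)
    in_left[lvl == L - 1] = 0
    left_rows = np.flatnonzero(in_left.astype(bool))
    return scores[b], np.nan, gmask, left_rows


def _score_numeric_batch(Yn, P, V, nsplit, min_child, rng, iu):
    """Score all candidate cuts of several numeric covariates at once.

    V : (m, F) in-node covariate values, columns in drawn order.  Returns
    (score, local_feature, threshold, left_rows) of the best admissible
    candidate, with ties broken feature-first then smallest cut, or None.
    """
    m, F = V.shape
    if m < 2 * min_child:
        return None
    order = np.argsort(V, axis=0, kind="stable")
    Vs = np.take_along_axis(V, order, axis=0)
    # cut with left size k is admissible iff it falls between distinct values
    ks = np.arange(min_child, m - min_child + 1)
    valid = Vs[ks] > Vs[ks - 1]  # (K, F)
    if not valid.any():
        return None
    K = len(ks)
    if K <= nsplit:
        chosen = valid
    else:
        # draw nsplit of each column's valid cuts uniformly without
        # replacement via random-key ranking (vectorized across features)
        keys = np.where(valid, rng.random((K, F)), np.inf)
        kth = np.partition(keys, nsplit - 1, axis=0)[nsplit - 1]
        chosen = valid & (keys <= kth[None, :])
    c1 = np.cumsum(Yn[order], axis=0)  # (m, F, q)
    c2 = np.cumsum(P[order], axis=0)  # (m, F, T)
    nL = ks.astype(np.float64)[:, None, None]
    nR = m - nL
    SL1 = c1[ks - 1]  # (K, F, q)
    SL2 = c2[ks - 1]
    SR1 = c1[-1][None] - SL1
    SR2 = c2[-1][None] - SL2
    covL = (SL2 - SL1[:, :, iu[0]] * SL1[:, :, iu[1]] / nL) / (nL - 1.0)
    covR = (SR2 - SR1[:, :, iu[0]] * SR1[:, :, iu[1]] / nR) / (nR - 1.0)
    d2 = ((covL - covR) ** 2).sum(axis=2)  # (K, F)
    scores = np.sqrt(np.maximum((nL * nR)[:, :, 0] * d2, 0.0))
    scores[~chosen] = -np.inf
    flat = np.argmax(scores.T)  # feature-major: drawn order, then cut asc
    f_best, k_pos = divmod(flat, len(ks))
    k = ks[k_pos]
    thr = 0.5 * (Vs[k - 1, f_best] + Vs[k, f_best])
    left_rows = order[:k, f_best]
    return scores[k_pos, f_best], int(f_best), float(thr), left_rows


def grow_tree(X, Y, is_categorical, inbag, params, rng) -> Tree:
    """Grow one tree on the in-bag rows.

    A node is terminal when it holds at most ``nodesize`` members, fewer than
    2*min_child members, or no admissible candidate split exists.  Among the
    proposed candidates the maximum-score split wins; ties go to the first
    candidate in drawn-covariate order with cut points ascending.
    """
    q = Y.shape[1]
    p = X.shape[1]
    iu = np.triu_indices(q)
    nodesize = params.nodesize
    min_child = params.min_child

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

    root = new_node(np.asarray(inbag, dtype=np.int64))
    stack = [root]
    while stack:
        v = stack.pop()
        idx = members[v]
        m = len(idx)
        if m <= nodesize or m < 2 * min_child:
            continue
        feats = rng.permutation(p)[: params.mtry]
        Yn = Y[idx]
        P = _pair_products(Yn, iu)
        best = None  # (score, feature, threshold, mask, left_rows)
        if not is_categorical[feats].any():
            res = _score_numeric_batch(
                Yn, P, X[idx][:, feats], params.nsplit, min_child, rng, iu
            )
            if res is not None:
                score, f_local, thr, left_rows = res
                best = (score, feats[f_local], thr, None, left_rows)
        else:
            for j in feats:
                col = X[idx, j]
                scorer = (
                    _score_categorical if is_categorical[j] else _score_numeric
                )
                res = scorer(Yn, P, col, params.nsplit, min_child, rng, iu)
                if res is None:
                    continue
                score, thr, gmask, left_rows = res
                if best is None or score > best[0]:
                    best = (score, j, thr, gmask, left_rows)
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
        stack.append(lid)
        stack.append(rid)

    return Tree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=np.float64),
        left_mask=np.asarray(left_mask, dtype=np.uint64),
        left_child=np.asarray(lchild, dtype=np.int64),
        right_child=np.asarray(rchild, dtype=np.int64),
        members=members,
    )


def route(tree: Tree, Xq: np.ndarray, is_categorical: np.ndarray) -> np.ndarray:
    """Route query rows to terminal nodes (no unseen categorical codes).

    Categorical codes must be valid training codes (>= 0); a level not in the
    node's left subset is routed right.
    """
    n = Xq.shape[0]
    node = np.zeros(n, dtype=np.int64)
    while True:
        f = tree.feature[node]
        active = f >= 0
        if not active.any():
            return node
        rows = np.flatnonzero(active)
        fa = f[rows]
        x = Xq[rows, fa]
        nd = node[rows]
        cat = is_categorical[fa]
        go_left = np.empty(len(rows), dtype=bool)
        if cat.any():
            codes = x[cat].astype(np.uint64)
            go_left[cat] = ((tree.left_mask[nd[cat]] >> codes) & np.uint64(1)).astype(bool)
        if (~cat).any():
            go_left[~cat] = x[~cat] <= tree.threshold[nd[~cat]]
        node[rows] = np.where(go_left, tree.left_child[nd], tree.right_child[nd])


def route_with_unseen(tree: Tree, Xq: np.ndarray, is_categorical: np.ndarray):
    """Route query rows, sending rows with unseen categorical codes (-1)
    down both children of any node splitting on that column.

    Returns (rows, leaves): parallel arrays of (query row, terminal node)
    pairs; a row appears once per terminal node it reaches.
    """
    out_rows, out_leaves = [], []
    stack = [(0, np.arange(Xq.shape[0]))]
    while stack:
        v, rows = stack.pop()
        if rows.size == 0:
            continue
        f = tree.feature[v]
        if f < 0:
            out_rows.append(rows)
            out_leaves.append(np.full(rows.size, v, dtype=np.int64))
            continue
        x = Xq[rows, f]
        if is_categorical[f]:
            unseen = x < 0
            codes = np.where(unseen, 0, x).astype(np.uint64)
            in_left = ((tree.left_mask[v] >> codes) & np.uint64(1)).astype(bool)
            stack.append((tree.left_child[v], rows[(in_left & ~unseen) | unseen]))
            stack.append((tree.right_child[v], rows[(~in_left & ~unseen) | unseen]))
        else:
            go_left = x <= tree.threshold[v]
            stack.append((tree.left_child[v], rows[go_left]))
            stack.append((tree.right_child[v], rows[~go_left]))
    if not out_rows:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(out_rows), np.concatenate(out_leaves)
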