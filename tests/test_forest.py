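"""Forest core: split kernels, candidate proposal, tree and forest growth."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from covforest import (
    DegenerateNodeError,
    SupervisedSample,
    grow_forest,
    node_covariance,
    propose_splits,
    split_score,
    upper_tri_distance,
)
from covforest._tree import grow_tree, route
from covforest.params import ForestParams


def exhaustive_best_split(X, Y, min_child=2):
    """Independent brute force over every covariate and threshold."""
    best, arg = -1.0, None
    for j in range(X.shape[1]):
        vs = np.unique(X[:, j])
        for t in 0.5 * (vs[1:] + vs[:-1]):
            L = np.flatnonzero(X[:, j] <= t)
            R = np.flatnonzero(X[:, j] > t)
            if len(L) < min_child or len(R) < min_child:
                continue
            sc = split_score(L, R, Y)
            if sc > best:
                best, arg = sc, (j, t, frozenset(L.tolist()))
    return best, arg


class TestNodeCovariance:
    def test_identical_rows_give_zero(self):
        Y = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert np.allclose(node_covariance([0, 1], Y), 0.0)

    def test_hand_computed(self):
        Y = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert np.allclose(
            node_covariance([0, 1], Y), [[2.0, 0.0], [0.0, 0.0]]
        )

    def test_matches_two_pass_oracle(self, rng):
        Y = rng.standard_normal((6, 3))
        rows = np.arange(6)
        mu = Y.mean(axis=0)
        oracle = sum(np.outer(y - mu, y - mu) for y in Y) / 5
        assert np.allclose(node_covariance(rows, Y), oracle, atol=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateNodeError):
            node_covariance([0], np.zeros((3, 2)))


class TestUpperTriDistance:
    def test_hand_cases(self):
        I2 = np.eye(2)
        E = np.array([[2.0, 1.0], [1.0, 2.0]])
        D = np.array([[4.0, 1.0], [1.0, 9.0]])
        assert upper_tri_distance(I2, I2) == 0.0
        assert upper_tri_distance(I2, E) == pytest.approx(np.sqrt(3), abs=1e-9)
        assert upper_tri_distance(D, I2) == pytest.approx(np.sqrt(74), abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            upper_tri_distance(np.eye(2), np.eye(3))

    @given(
        arrays(np.float64, (3, 3), elements=st.floats(-5, 5)),
        arrays(np.float64, (3, 3), elements=st.floats(-5, 5)),
        arrays(np.float64, (3, 3), elements=st.floats(-5, 5)),
    )
    def test_is_a_metric(self, A, B, C):
        A, B, C = [0.5 * (M + M.T) for M in (A, B, C)]
        dab = upper_tri_distance(A, B)
        assert dab >= 0
        assert dab == pytest.approx(upper_tri_distance(B, A))
        if np.array_equal(A, B):
            assert dab == 0
        assert dab <= upper_tri_distance(A, C) + upper_tri_distance(C, B) + 1e-9


class TestSplitScore:
    def test_constant_response_scores_zero(self):
        Y = np.ones((8, 2))
        assert split_score(np.arange(4), np.arange(4, 8), Y) == 0.0

    def test_composes_distance_and_sizes(self, rng):
        L = rng.standard_normal((4, 2))
        R = rng.standard_normal((4, 2))
        Y = np.vstack([L, R])
        expected = 4.0 * upper_tri_distance(
            node_covariance(np.arange(4), Y),
            node_covariance(np.arange(4, 8), Y),
        )
        got = split_score(np.arange(4), np.arange(4, 8), Y)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_left_right_relabeling_invariance(self, rng):
        Y = rng.standard_normal((10, 2))
        L, R = np.arange(5), np.arange(5, 10)
        assert split_score(L, R, Y) == pytest.approx(split_score(R, L, Y))


class TestProposeSplits:
    def test_constant_covariates_give_empty_list(self, rng):
        X = np.ones((8, 2))
        cands = propose_splits(
            np.arange(8), X, np.zeros(2, bool), rng, mtry=2, nsplit=5
        )
        assert cands == []

    def test_exhaustive_mode_matches_enumeration(self, rng):
        X = rng.standard_normal((10, 2))
        cands = propose_splits(
            np.arange(10), X, np.zeros(2, bool), rng, mtry=2, nsplit=10_000
        )
        # expected: all midpoint cuts with both children >= 2
        expected = 0
        for j in range(2):
            vs = np.unique(X[:, j])
            ks = np.array(
                [np.sum(X[:, j] <= t) for t in 0.5 * (vs[1:] + vs[:-1])]
            )
            expected += int(((ks >= 2) & (10 - ks >= 2)).sum())
        assert len(cands) == expected
        for c in cands:
            assert len(c.left_rows) >= 2 and len(c.right_rows) >= 2
            assert set(c.left_rows) | set(c.right_rows) == set(range(10))

    def test_binary_categorical_single_partition(self, rng):
        X = np.array([[0.0], [1.0], [0.0], [1.0], [0.0], [1.0]])
        cands = propose_splits(
            np.arange(6), X, np.ones(1, bool), rng, mtry=1, nsplit=50
        )
        assert len(cands) == 1
        assert cands[0].left_levels == (0,)


class TestGrowTree:
    def test_nodesize_at_sampsize_gives_root_only(self, small_sample):
        params = ForestParams(
            n_trees=1, nodesize=40, sampsize=40, seed=0
        ).resolve(60, 3, 2)
        tree = grow_tree(
            small_sample.X,
            small_sample.Y,
            small_sample.is_categorical,
            np.arange(40),
            params,
            np.random.default_rng(0),
        )
        assert tree.n_nodes == 1 and tree.feature[0] == -1

    def test_deterministic_given_seed(self, small_sample):
        params = ForestParams(n_trees=1, nodesize=8, sampsize=40, seed=0).resolve(
            60, 3, 2
        )
        args = (
            small_sample.X,
            small_sample.Y,
            small_sample.is_categorical,
            np.arange(40),
            params,
        )
        t1 = grow_tree(*args, np.random.default_rng(5))
        t2 = grow_tree(*args, np.random.default_rng(5))
        assert np.array_equal(t1.feature, t2.feature)
        assert np.array_equal(t1.threshold, t2.threshold, equal_nan=True)

    def test_regime_separating_covariate_chosen_at_root(self, small_sample):
        # X1 flips the response correlation sign; with exhaustive candidates
        # the root split must use it
        params = ForestParams(
            n_trees=1, mtry=3, nsplit=10_000, nodesize=10, sampsize=59, seed=0
        ).resolve(60, 3, 2)
        tree = grow_tree(
            small_sample.X,
            small_sample.Y,
            small_sample.is_categorical,
            np.arange(60),
            params,
            np.random.default_rng(1),
        )
        assert tree.feature[0] == 0

    def test_children_partition_parent_and_routing_consistent(
        self, small_sample, small_params
    ):
        forest = grow_forest(small_sample, small_params)
        tree = forest.trees[0]
        for v in range(tree.n_nodes):
            if tree.feature[v] < 0:
                continue
            l, r = tree.left_child[v], tree.right_child[v]
            got = np.sort(np.r_[tree.members[l], tree.members[r]])
            assert np.array_equal(got, np.sort(tree.members[v]))
        # every in-bag row routes to the terminal node listing it
        leaves = route(
            tree, small_sample.X[forest.inbag[0]], small_sample.is_categorical
        )
        for row, leaf in zip(forest.inbag[0], leaves):
            assert row in tree.members[leaf]

    def test_root_split_attains_global_maximum(self, rng):
        # tiny-n oracle: exhaustive candidate mode vs brute-force enumeration
        for trial in range(10):
            n = int(rng.integers(8, 13))
            p = int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            Y = rng.standard_normal((n, 2))
            params = ForestParams(
                n_trees=1, mtry=p, nsplit=10_000, nodesize=3,
                sampsize=n - 1, seed=trial,
            ).resolve(n, p, 2)
            tree = grow_tree(
                X, Y, np.zeros(p, bool), np.arange(n), params,
                np.random.default_rng(trial),
            )
            best, arg = exhaustive_best_split(X, Y)
            if arg is None:
                assert tree.feature[0] == -1
                continue
            left = frozenset(tree.members[tree.left_child[0]].tolist())
            chosen = split_score(
                sorted(left), sorted(set(range(n)) - left), Y
            )
            assert chosen == pytest.approx(best, rel=1e-10)


class TestGrowForest:
    def test_inbag_size_and_distinctness(self, small_sample, small_params):
        forest = grow_forest(small_sample, small_params)
        expect = int(0.632 * 60)
        for ib, ob in zip(forest.inbag, forest.oob):
            assert len(ib) == expect == len(np.unique(ib))
            assert len(np.intersect1d(ib, ob)) == 0
            assert len(ib) + len(ob) == 60

    def test_every_row_eventually_oob(self, small_sample, small_params):
        forest = grow_forest(small_sample, small_params)
        oob_union = np.unique(np.concatenate(forest.oob))
        assert len(oob_union) == 60

    def test_seed_reproducibility(self, small_sample, small_params):
        f1 = grow_forest(small_sample, small_params)
        f2 = grow_forest(small_sample, small_params)
        for t1, t2 in zip(f1.trees, f2.trees):
            assert np.array_equal(t1.feature, t2.feature)
            for m1, m2 in zip(t1.members, t2.members):
                assert np.array_equal(m1, m2)

    def test_sampsize_too_small_rejected(self, small_sample):
        with pytest.raises(ValueError):
            grow_forest(
                small_sample,
                ForestParams(n_trees=2, nodesize=10, sampsize=3, seed=0),
            )
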