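"""BOP construction and covariance estimation against brute-force oracles."""

import numpy as np
import pytest

from covforest import (
    DegenerateNodeError,
    bop_for_new,
    bop_for_training,
    estimate_covariance,
    grow_forest,
    node_covariance,
    oob_estimates,
)
from covforest.params import ForestParams


def route_one_oracle(tree, x, is_cat):
    """Independent single-row traversal used as the routing oracle."""
    v = 0
    while tree.feature[v] >= 0:
        f = tree.feature[v]
        if is_cat[f]:
            go_left = bool(
                (int(tree.left_mask[v]) >> int(x[f])) & 1
            )
        else:
            go_left = x[f] <= tree.threshold[v]
        v = tree.left_child[v] if go_left else tree.right_child[v]
    return v


def bop_oracle_new(forest, x):
    """Definition-level BOP for a new point: union over trees of OOB rows in
    the same terminal node."""
    members = set()
    is_cat = forest.sample.is_categorical
    for tree, ob in zip(forest.trees, forest.oob):
        leaf = route_one_oracle(tree, x, is_cat)
        for j in ob:
            if route_one_oracle(tree, forest.sample.X[j], is_cat) == leaf:
                members.add(int(j))
    return members


def bop_oracle_training(forest, i, exclude_self=True):
    members = set()
    is_cat = forest.sample.is_categorical
    for tree, ob in zip(forest.trees, forest.oob):
        if i not in ob:
            continue
        leaf = route_one_oracle(tree, forest.sample.X[i], is_cat)
        for j in ob:
            if j == i and exclude_self:
                continue
            if route_one_oracle(tree, forest.sample.X[j], is_cat) == leaf:
                members.add(int(j))
    return members


@pytest.fixture
def fitted(small_sample, small_params):
    return grow_forest(small_sample, small_params)


class TestBopForNew:
    def test_matches_traversal_oracle(self, fitted, rng):
        for _ in range(5):
            x = rng.standard_normal(3)
            got = set(bop_for_new(fitted, x).members.tolist())
            assert got == bop_oracle_new(fitted, x)

    def test_root_only_forest_unions_all_oob(self, small_sample):
        params = ForestParams(n_trees=10, nodesize=59, sampsize=37, seed=2)
        forest = grow_forest(small_sample, params)
        ns = bop_for_new(forest, np.zeros(3))
        expect = set(np.unique(np.concatenate(forest.oob)).tolist())
        assert set(ns.members.tolist()) == expect

    def test_per_tree_union_semantics(self, fitted):
        ns = bop_for_new(fitted, np.zeros(3))
        assert set(ns.members.tolist()) == set(
            int(v) for arr in ns.per_tree.values() for v in arr
        )


class TestBopForTraining:
    def test_matches_oracle_and_excludes_self(self, fitted):
        for i in (0, 7, 31):
            ns = bop_for_training(fitted, i)
            assert i not in ns.members
            assert set(ns.members.tolist()) == bop_oracle_training(fitted, i)

    def test_inbag_trees_contribute_nothing(self, fitted):
        ns = bop_for_training(fitted, 3)
        for b in ns.per_tree:
            assert 3 in fitted.oob[b]

    def test_include_self_flag(self, fitted):
        ns = bop_for_training(fitted, 5, exclude_self=False)
        assert set(ns.members.tolist()) == bop_oracle_training(
            fitted, 5, exclude_self=False
        )


class TestEstimateCovariance:
    def test_training_estimates_match_bop_definition(self, fitted):
        ests = oob_estimates(fitted)
        for i in (0, 11, 42):
            ns = bop_for_training(fitted, i)
            if len(ns.members) >= 2:
                expect = node_covariance(ns.members, fitted.sample.Y)
                assert np.allclose(ests[i].matrix, expect)
                assert ests[i].bop_size == len(ns.members)

    def test_query_estimates_match_bop_definition(self, fitted, rng):
        Xq = rng.standard_normal((4, 3))
        ests = estimate_covariance(fitted, Xq)
        for r in range(4):
            members = sorted(bop_oracle_new(fitted, Xq[r]))
            expect = node_covariance(members, fitted.sample.Y)
            assert np.allclose(ests[r].matrix, expect)

    def test_constant_response_gives_zero_matrix(self, rng):
        from covforest import SupervisedSample

        X = rng.standard_normal((40, 2))
        Y = np.tile([1.0, 2.0], (40, 1))
        s = SupervisedSample(X=X, Y=Y, is_categorical=np.zeros(2, bool))
        forest = grow_forest(s, ForestParams(n_trees=20, nodesize=10, seed=0))
        ests = estimate_covariance(forest, X[:3])
        for e in ests:
            assert np.allclose(e.matrix, 0.0)

    def test_degenerate_raises_by_default(self, small_sample):
        # a single root-only tree: a query's BOP can be fine, but training
        # rows that are never OOB must raise in bop_for_training
        params = ForestParams(n_trees=1, nodesize=59, sampsize=58, seed=0)
        forest = grow_forest(small_sample, params)
        inbag_only = set(forest.inbag[0]) - set(forest.oob[0])
        i = sorted(inbag_only)[0]
        with pytest.raises(ValueError, match="n_trees"):
            bop_for_training(forest, i)
        # and degenerate BOPs raise in estimation unless told otherwise
        ests = oob_estimates(forest, on_degenerate="nan")
        assert any(e.degenerate for e in ests)
        with pytest.raises(DegenerateNodeError):
            oob_estimates(forest, on_degenerate="raise")

    def test_multiset_semantics_pool_with_multiplicity(self, fitted):
        ests_set = oob_estimates(fitted, multiset=False)
        ests_multi = oob_estimates(fitted, multiset=True)
        # same neighbour support, potentially different weighting
        assert all(
            a.bop_size == b.bop_size for a, b in zip(ests_set, ests_multi)
        )
        diffs = [
            np.abs(a.matrix - b.matrix).max()
            for a, b in zip(ests_set, ests_multi)
            if not (a.degenerate or b.degenerate)
        ]
        assert max(diffs) > 0  # multiplicity actually changes the weighting


class TestLocalization:
    def test_lower_nodesize_weakly_shrinks_median_bop(self, small_sample):
        sizes = {}
        for ns in (5, 20, 45):
            params = ForestParams(n_trees=30, nodesize=ns, seed=4)
            forest = grow_forest(small_sample, params)
            ests = oob_estimates(forest, on_degenerate="nan")
            sizes[ns] = np.median(
                [e.bop_size for e in ests if not e.degenerate]
            )
        assert sizes[5] <= sizes[20] <= sizes[45]

    def test_row_permutation_equivariance(self, small_sample, small_params):
        """Re-ordering training rows while transporting the per-tree
        subsample assignment leaves every estimate unchanged."""
        from covforest._tree import grow_tree
        from covforest.forest import ForestModel

        f1 = grow_forest(small_sample, small_params)
        perm = np.random.default_rng(9).permutation(small_sample.n)
        inv = np.argsort(perm)
        s2 = small_sample.with_X(small_sample.X[perm])
        s2.Y = small_sample.Y[perm]
        params = small_params.resolve(60, 3, 2)
        trees, inbags, oobs = [], [], []
        ss = np.random.SeedSequence(params.seed)
        for b, child in enumerate(ss.spawn(params.n_trees)):
            rng_b = np.random.default_rng(child)
            ib_orig = np.sort(
                rng_b.choice(60, size=params.sampsize, replace=False)
            )
            ib = np.sort(inv[ib_orig])  # transported subsample
            tree = grow_tree(s2.X, s2.Y, s2.is_categorical, ib, params, rng_b)
            trees.append(tree)
            inbags.append(ib)
            oobs.append(np.setdiff1d(np.arange(60), ib, assume_unique=True))
        f2 = ForestModel(
            sample=s2, params=params, trees=trees, inbag=inbags, oob=oobs
        )
        e1 = oob_estimates(f1, on_degenerate="nan")
        e2 = oob_estimates(f2, on_degenerate="nan")
        for i in range(60):
            a, b = e1[i], e2[inv[i]]
            if a.degenerate or b.degenerate:
                assert a.degenerate == b.degenerate
            else:
                assert np.allclose(a.matrix, b.matrix)
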