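"""Permutation tests for covariate effects on the conditional covariance.

Global test: H0 says the conditional covariance given all covariates equals
the unconditional covariance of Y (the "root" estimate).  Partial test: H0
says the conditional covariance given all covariates equals the one given
the control subset only, i.e. the tested covariates add nothing.

Both use the statistic T = mean_i d(Sigma_hat_full(x_i), Sigma_hat_ctrl(x_i))
with d the upper-triangular Euclidean distance, and build the null by
refitting on data where the rows of the *tested* covariate block are
permuted (Y and the control columns fixed).  For the global test the tested
block is all of X, so whole covariate rows are permuted; for the partial
test only the non-control columns are shuffled (as a block, preserving
their joint distribution), which keeps the control model calibrated under
the null — permuting the control columns too would destroy their real
association with Y and grossly inflate the type-I error.  Nodesize is tuned
once on the original data and reused across permutations.  The global test
refits one forest per permutation (R + 1 forests in total); the partial
test refits two (2R + 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bop import oob_estimates
from .forest import grow_forest, node_covariance, upper_tri_distance
from .params import ForestParams
from .sample import SupervisedSample
from .tuning import tune_nodesize

__all__ = [
    "PermutationTestResult",
    "test_statistic",
    "global_test",
    "partial_test",
]


@dataclass
class PermutationTestResult:
    """Observed statistic, permutation replicates and p-value estimates.

    ``p_value`` uses the strict-inequality estimate (1/R) #{T_r > T}, which
    can legitimately be 0; ``p_value_smoothed`` is the conventional
    (1 + #{T_r >= T}) / (1 + R) for users needing a nonzero guarantee.
    """

    statistic: float
    perm_stats: np.ndarray
    p_value: float
    p_value_smoothed: float
    n_permutations: int
    test_type: str
    nodesize_full: int
    nodesize_control: int | None = None
    control_columns: tuple | None = None

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def test_statistic(full_estimates, control_estimates) -> float:
    """Mean over observations of the upper-triangular distance between the
    paired covariance estimates.  Pairs with any non-finite entry (degenerate
    BOPs) are dropped from the mean."""
    if len(full_estimates) != len(control_estimates):
        raise ValueError("estimate lists must have equal length")
    dists = []
    for F, C in zip(full_estimates, control_estimates):
        F = np.asarray(getattr(F, "matrix", F), dtype=float)
        C = np.asarray(getattr(C, "matrix", C), dtype=float)
        if not (np.isfinite(F).all() and np.isfinite(C).all()):
            continue
        dists.append(upper_tri_distance(F, C))
    if not dists:
        raise ValueError("no valid estimate pairs")
    return float(np.mean(dists))


def _oob_matrices(forest) -> list[np.ndarray]:
    return [e.matrix for e in oob_estimates(forest, on_degenerate="nan")]


def _forest_seeds(master: int | None, count: int) -> np.ndarray:
    """Derive reproducible per-forest seeds from the master seed."""
    return np.random.SeedSequence(master).generate_state(count)


def global_test(
    sample: SupervisedSample,
    n_permutations: int = 500,
    params: ForestParams | None = None,
) -> PermutationTestResult:
    """Test the global effect of the covariates on the covariance estimates.

    H0: the conditional covariance equals the unconditional sample
    covariance of Y.  One forest is fitted per sample; the nodesize tuned on
    the original data is reused for every permutation refit.
    """
    params = (params or ForestParams()).resolve(sample.n, sample.p, sample.q)
    R = int(n_permutations)
    if R < 1:
        raise ValueError("need at least one permutation")
    seeds = _forest_seeds(params.seed, R + 2)
    if params.nodesize is None:
        nodesize, _ = tune_nodesize(sample, replace(params, seed=int(seeds[0])))
    else:
        nodesize = params.nodesize
    fit_params = replace(params, nodesize=nodesize, seed=int(seeds[0]))
    sigma_root = node_covariance(np.arange(sample.n), sample.Y)
    full = _oob_matrices(grow_forest(sample, fit_params))
    T = test_statistic(full, [sigma_root] * sample.n)
    rng = np.random.default_rng(np.random.SeedSequence([0x9E37, seeds[R + 1]]))
    T_perm = np.empty(R)
    for r in range(R):
        perm = rng.permutation(sample.n)
        sample_r = sample.with_X(sample.X[perm])
        forest_r = grow_forest(
            sample_r, replace(fit_params, seed=int(seeds[r + 1]))
        )
        T_perm[r] = test_statistic(
            _oob_matrices(forest_r), [sigma_root] * sample.n
        )
    return PermutationTestResult(
        statistic=T,
        perm_stats=T_perm,
        p_value=float(np.mean(T_perm > T)),
        p_value_smoothed=float((1 + np.sum(T_perm >= T)) / (1 + R)),
        n_permutations=R,
        test_type="global",
        nodesize_full=nodesize,
    )


def partial_test(
    sample: SupervisedSample,
    control_columns,
    n_permutations: int = 500,
    params: ForestParams | None = None,
    control_nodesize: int | None = None,
    permute: str = "tested",
) -> PermutationTestResult:
    """Test the effect of the non-control covariates while controlling for
    ``control_columns``.

    H0: the conditional covariance given all covariates equals the one given
    the control covariates only.  Two forests are fitted per sample (full
    and control); nodesizes are tuned separately on the original data and
    reused for every permutation refit.  ``permute`` selects the null
    scheme: ``"tested"`` (default) shuffles only the rows of the tested
    covariate block, keeping the control columns aligned with Y;
    ``"all"`` shuffles whole rows of X (anti-conservative when the control
    covariates carry signal; kept for comparison).
    """
    if permute not in ("tested", "all"):
        raise ValueError("permute must be 'tested' or 'all'")
    control = tuple(sorted(int(c) for c in control_columns))
    if len(control) == 0:
        return global_test(sample, n_permutations, params)
    if not all(0 <= c < sample.p for c in control):
        raise ValueError("control columns out of range")
    if len(set(control)) == sample.p:
        raise ValueError(
            "control set covers every covariate; nothing left to test"
        )
    params = (params or ForestParams()).resolve(sample.n, sample.p, sample.q)
    R = int(n_permutations)
    if R < 1:
        raise ValueError("need at least one permutation")
    ctrl_sample = sample.subset_columns(control)
    # the control model has its own p, so re-resolve mtry for it
    base_ctrl = ForestParams(
        n_trees=params.n_trees,
        nsplit=params.nsplit,
        sampsize=params.sampsize,
        min_child=params.min_child,
        nodesize=control_nodesize,
    ).resolve(ctrl_sample.n, ctrl_sample.p, ctrl_sample.q)
    seeds = _forest_seeds(params.seed, 2 * R + 3)
    if params.nodesize is None:
        ns_full, _ = tune_nodesize(sample, replace(params, seed=int(seeds[0])))
    else:
        ns_full = params.nodesize
    if base_ctrl.nodesize is None:
        ns_ctrl, _ = tune_nodesize(
            ctrl_sample, replace(base_ctrl, seed=int(seeds[1]))
        )
    else:
        ns_ctrl = base_ctrl.nodesize
    fit_full = replace(params, nodesize=ns_full, seed=int(seeds[0]))
    fit_ctrl = replace(base_ctrl, nodesize=ns_ctrl, seed=int(seeds[1]))
    full = _oob_matrices(grow_forest(sample, fit_full))
    ctrl = _oob_matrices(grow_forest(ctrl_sample, fit_ctrl))
    T = test_statistic(full, ctrl)
    tested = np.array(
        [j for j in range(sample.p) if j not in set(control)], dtype=int
    )
    rng = np.random.default_rng(np.random.SeedSequence([0x9E37, seeds[-1]]))
    T_perm = np.empty(R)
    for r in range(R):
        perm = rng.permutation(sample.n)
        Xp = sample.X.copy()
        if permute == "all":
            Xp = Xp[perm]
        else:  # permute the tested block as whole rows, controls fixed
            Xp[:, tested] = Xp[np.ix_(perm, tested)]
        sample_r = sample.with_X(Xp)
        ctrl_r = sample_r.subset_columns(control)
        full_r = _oob_matrices(
            grow_forest(sample_r, replace(fit_full, seed=int(seeds[2 + 2 * r])))
        )
        ctrl_est_r = _oob_matrices(
            grow_forest(ctrl_r, replace(fit_ctrl, seed=int(seeds[3 + 2 * r])))
        )
        T_perm[r] = test_statistic(full_r, ctrl_est_r)
    return PermutationTestResult(
        statistic=T,
        perm_stats=T_perm,
        p_value=float(np.mean(T_perm > T)),
        p_value_smoothed=float((1 + np.sum(T_perm >= T)) / (1 + R)),
        n_permutations=R,
        test_type="partial",
        nodesize_full=ns_full,
        nodesize_control=ns_ctrl,
        control_columns=control,
    )
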