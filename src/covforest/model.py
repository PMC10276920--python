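"""User-facing model and results objects.

``CovarianceForest`` holds the data; ``fit()`` grows the forest (tuning the
nodesize from the data when it is not given) and returns a
``CovarianceForestResults`` carrying the fitted forest, the per-row
out-of-bag covariance estimates, prediction, the permutation tests and the
variable-importance measure.

Example
-------
>>> from covforest import CovarianceForest, dgp1
>>> sim = dgp1(n=200, seed=7)
>>> res = CovarianceForest(sim.Y, sim.X).fit(n_trees=200, seed=7)
>>> res.predict(sim.X[:3]).shape
(3, 2, 2)
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .bop import estimate_covariance, oob_estimates
from .forest import grow_forest, node_covariance
from .params import ForestParams
from .sample import SupervisedSample
from .significance import PermutationTestResult, global_test, partial_test
from .tuning import TuningTrace, tune_nodesize
from .vimp import VimpResult, compute_vimp

__all__ = ["CovarianceForest", "CovarianceForestResults"]


class CovarianceForest:
    """Covariance regression with random forests.

    Models the conditional covariance matrix Sigma_x = Cov[y | x] of a
    q-variate response as a nonparametric function of covariates, by growing
    trees whose splits maximize the between-child difference in sample
    covariance matrices and estimating Sigma_x from each query's out-of-bag
    nearest-neighbour set.

    Parameters
    ----------
    Y : array-like or DataFrame, shape (n, q), q >= 2
        Numeric responses.
    X : array-like or DataFrame, shape (n, p)
        Covariates; non-numeric DataFrame columns are treated as categorical.
    """

    def __init__(self, Y, X):
        if isinstance(X, pd.DataFrame) or isinstance(Y, pd.DataFrame):
            self.data = SupervisedSample.from_frames(
                pd.DataFrame(Y), pd.DataFrame(X)
            )
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            self.data = SupervisedSample(
                X=X,
                Y=np.asarray(Y, dtype=float),
                is_categorical=np.zeros(X.shape[1], dtype=bool),
            )

    @classmethod
    def from_frames(cls, Y: pd.DataFrame, X: pd.DataFrame) -> "CovarianceForest":
        return cls(Y, X)

    def fit(
        self,
        n_trees: int = 1000,
        nodesize: int | None = None,
        mtry: int | None = None,
        nsplit: int | None = None,
        sampsize: int | None = None,
        min_child: int = 2,
        seed: int | None = None,
    ) -> "CovarianceForestResults":
        """Grow the forest; tune nodesize from the data when not given."""
        params = ForestParams(
            n_trees=n_trees,
            mtry=mtry,
            nsplit=nsplit,
            nodesize=nodesize,
            sampsize=sampsize,
            min_child=min_child,
            seed=seed,
        ).resolve(self.data.n, self.data.p, self.data.q)
        trace = None
        if params.nodesize is None:
            selected, trace = tune_nodesize(self.data, params)
            params = replace(params, nodesize=selected)
        forest = grow_forest(self.data, params)
        return CovarianceForestResults(self, forest, params, trace)


class CovarianceForestResults:
    """Fitted covariance forest: estimates, tests and importances."""

    def __init__(self, model, forest, params, tuning_trace: TuningTrace | None):
        self.model = model
        self.forest = forest
        self.params = params
        self.nodesize = params.nodesize
        self.tuning_trace = tuning_trace
        self._oob_cache = None

    # ---- estimates -------------------------------------------------------

    @property
    def oob_estimates(self):
        """Per-training-row OOB covariance estimates (degenerate rows NaN)."""
        if self._oob_cache is None:
            self._oob_cache = oob_estimates(self.forest, on_degenerate="nan")
        return self._oob_cache

    @property
    def oob_matrices(self) -> np.ndarray:
        return np.array([e.matrix for e in self.oob_estimates])

    @property
    def sigma_root(self) -> np.ndarray:
        """Unconditional sample covariance of the responses."""
        return node_covariance(np.arange(self.model.data.n), self.model.data.Y)

    def predict(self, X_new, on_degenerate: str = "raise") -> np.ndarray:
        """Conditional covariance estimates for new covariate rows, (m, q, q)."""
        ests = estimate_covariance(
            self.forest, X_new, on_degenerate=on_degenerate
        )
        return np.array([e.matrix for e in ests])

    def predict_frame(self, X_new, on_degenerate: str = "raise") -> pd.DataFrame:
        """Predictions as a flat table: one column per upper-triangle entry
        (sigma_<Yj>_<Yk>, j <= k) plus the BOP size used."""
        ests = estimate_covariance(
            self.forest, X_new, on_degenerate=on_degenerate
        )
        ynames = self.model.data.y_names
        q = self.model.data.q
        iu = np.triu_indices(q)
        cols = {
            f"sigma_{ynames[j]}_{ynames[k]}": [e.matrix[j, k] for e in ests]
            for j, k in zip(*iu)
        }
        cols["bop_size"] = [e.bop_size for e in ests]
        return pd.DataFrame(cols)

    # ---- inference -------------------------------------------------------

    def _test_params(self, n_trees, seed):
        return replace(
            self.params,
            n_trees=n_trees if n_trees is not None else self.params.n_trees,
            seed=seed if seed is not None else self.params.seed,
        )

    def global_test(
        self,
        n_permutations: int = 500,
        n_trees: int | None = None,
        seed: int | None = None,
    ) -> PermutationTestResult:
        """Permutation test of the global covariate effect (H0: the
        conditional covariance equals the unconditional one)."""
        return global_test(
            self.model.data,
            n_permutations=n_permutations,
            params=self._test_params(n_trees, seed),
        )

    def partial_test(
        self,
        control,
        n_permutations: int = 500,
        n_trees: int | None = None,
        seed: int | None = None,
    ) -> PermutationTestResult:
        """Permutation test of the covariates outside ``control`` (names or
        indices), controlling for those inside."""
        control_idx = self._resolve_columns(control)
        params = replace(self._test_params(n_trees, seed), nodesize=None)
        return partial_test(
            self.model.data,
            control_idx,
            n_permutations=n_permutations,
            params=replace(params, nodesize=self.nodesize),
        )

    def variable_importance(
        self,
        n_trees: int = 1000,
        nodesize: int = 5,
        seed: int | None = None,
    ) -> VimpResult:
        """Fit-the-fit permutation importances of the covariates."""
        return compute_vimp(
            self.model.data,
            self.oob_estimates,
            n_trees=n_trees,
            nodesize=nodesize,
            seed=seed if seed is not None else self.params.seed,
        )

    def _resolve_columns(self, cols):
        names = self.model.data.x_names
        out = []
        for c in cols:
            if isinstance(c, str):
                if c not in names:
                    raise ValueError(f"unknown covariate {c!r}")
                out.append(names.index(c))
            else:
                out.append(int(c))
        return out

    # ---- reporting -------------------------------------------------------

    def summary(self) -> str:
        d = self.model.data
        valid = [e for e in self.oob_estimates if not e.degenerate]
        bops = [e.bop_size for e in valid]
        lines = [
            "Covariance Regression Forest Results",
            "=" * 38,
            f"No. observations:      {d.n}",
            f"No. covariates:        {d.p}",
            f"No. responses:         {d.q}",
            f"Trees:                 {self.params.n_trees}",
            f"mtry / nsplit:         {self.params.mtry} / {self.params.nsplit}",
            f"sampsize:              {self.params.sampsize}",
            f"nodesize:              {self.nodesize}"
            + (" (tuned)" if self.tuning_trace is not None else ""),
            f"OOB estimates:         {len(valid)}/{d.n} rows",
            f"median BOP size:       {int(np.median(bops)) if bops else 0}",
        ]
        if self.tuning_trace is not None:
            grid = ", ".join(str(g) for g in self.tuning_trace.grid)
            mads = ", ".join(f"{m:.4f}" for m in self.tuning_trace.mad)
            lines += [f"nodesize grid:         {grid}", f"MAD trace:             {mads}"]
        return "\n".join(lines)

    def save(self, path) -> None:
        from .io import save_model

        save_model(self, path)
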