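"""Nodesize selection by out-of-bag estimate stability.

The estimation target (a conditional covariance matrix) is never observed,
so the usual OOB-error tuning is unavailable.  Instead, one forest is grown
per candidate nodesize and the nodesize whose OOB estimates change least
when moving to the next coarser level is selected: the mean absolute
difference (MAD) between per-row OOB estimates at consecutive candidate
levels is minimized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .bop import oob_estimates
from .forest import grow_forest
from .params import ForestParams
from .sample import SupervisedSample

__all__ = ["TuningTrace", "candidate_grid", "mad_between", "tune_nodesize"]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def candidate_grid(sampsize: int, q: int) -> list[int]:
    """Candidate nodesizes: round(sampsize / 2^k), k = 1, 2, ..., kept while
    strictly greater than q, returned ascending.

    Candidates at or below q are excluded because node covariances with at
    most q members are singular.
    """
    grid = []
    k = 1
    while True:
        val = _round_half_away(sampsize * 2.0 ** (-k))
        if val <= q:
            break
        grid.append(val)
        k += 1
    if not grid:
        raise ValueError(
            f"no admissible nodesize: sampsize/2 = {sampsize / 2} <= q = {q}; "
            "increase the sample size or reduce the response dimension"
        )
    return sorted(grid)


def mad_between(D: np.ndarray, E: np.ndarray) -> float:
    """Mean absolute difference over the upper triangle (diagonal included):
    2/(q(q+1)) * sum_{i<=j} |D_ij - E_ij|."""
    D = np.asarray(D, dtype=float)
    E = np.asarray(E, dtype=float)
    if D.shape != E.shape:
        raise ValueError(f"incompatible shapes {D.shape} and {E.shape}")
    q = D.shape[0]
    iu = np.triu_indices(q)
    return float(np.abs(D[iu] - E[iu]).sum() * 2.0 / (q * (q + 1)))


@dataclass
class TuningTrace:
    """Audit record of one tuning run."""

    grid: list
    mad: list  # MAD_j for consecutive pairs (len M-1)
    selected: int
    n_rows_used: int


def tune_nodesize(
    sample: SupervisedSample, params: ForestParams
) -> tuple[int, TuningTrace]:
    """Select nodesize minimizing the consecutive-level MAD of OOB estimates.

    One forest per candidate is grown with common per-tree subsamples (the
    master seed fixes the subsample-to-tree mapping), MAD_j is averaged over
    the training rows with valid OOB estimates at every level, and the
    candidate s(argmin_j MAD_j), j = 1..M-1, is returned; ties break to the
    smallest j.  The largest candidate s(M) is never selected.
    """
    params = params.resolve(sample.n, sample.p, sample.q)
    grid = candidate_grid(params.sampsize, sample.q)
    if len(grid) == 1:
        warnings.warn(
            "single-candidate nodesize grid; no MAD comparison possible",
            stacklevel=2,
        )
        return grid[0], TuningTrace(
            grid=grid, mad=[], selected=grid[0], n_rows_used=0
        )
    per_level = []
    for s in grid:
        forest = grow_forest(sample, replace(params, nodesize=s))
        ests = oob_estimates(forest, on_degenerate="nan")
        per_level.append(ests)
    # rows with a valid estimate at every level
    valid = np.ones(sample.n, dtype=bool)
    for ests in per_level:
        valid &= np.array([not e.degenerate for e in ests])
    rows = np.flatnonzero(valid)
    if rows.size == 0:
        raise ValueError(
            "no training row has valid OOB estimates at every nodesize level"
        )
    mads = []
    for j in range(len(grid) - 1):
        vals = [
            mad_between(per_level[j][i].matrix, per_level[j + 1][i].matrix)
            for i in rows
        ]
        mads.append(float(np.mean(vals)))
    best = int(np.argmin(mads))  # ties: smallest j
    selected = grid[best]
    return selected, TuningTrace(
        grid=grid, mad=mads, selected=selected, n_rows_used=int(rows.size)
    )
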