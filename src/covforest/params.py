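"""Forest hyper-parameters and their data-dependent defaults."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ForestParams:
    """Hyper-parameters of the covariance forest.

    Defaults follow the package's standard configuration: 1000 trees,
    mtry = ceil(p/3), nsplit = max(n/50, 10) random cut points per covariate,
    sub-sampling without replacement with sampsize = floor(0.632 n).
    ``nodesize`` is the stop-splitting threshold (nodes with at most
    ``nodesize`` members are terminal); when None it is tuned from the data.
    ``min_child`` guarantees both child covariance matrices are computable.
    """

    n_trees: int = 1000
    mtry: int | None = None
    nsplit: int | None = None
    nodesize: int | None = None
    sampsize: int | None = None
    min_child: int = 2
    seed: int | None = None

    def resolve(self, n: int, p: int, q: int) -> "ForestParams":
        """Fill data-dependent defaults and validate against (n, p, q)."""
        mtry = self.mtry if self.mtry is not None else math.ceil(p / 3)
        nsplit = (
            self.nsplit
            if self.nsplit is not None
            else max(math.ceil(n / 50), 10)
        )
        sampsize = (
            self.sampsize if self.sampsize is not None else int(0.632 * n)
        )
        out = replace(
            self, mtry=mtry, nsplit=nsplit, sampsize=sampsize
        )
        out.validate(n, p, q)
        return out

    def validate(self, n: int, p: int, q: int) -> None:
        if not (1 <= self.mtry <= p):
            raise ValueError(f"mtry={self.mtry} outside [1, p={p}]")
        if self.nsplit < 1:
            raise ValueError("nsplit must be >= 1")
        if self.min_child < 2:
            raise ValueError("min_child must be >= 2")
        if self.sampsize is None or not (2 * self.min_child <= self.sampsize < n):
            raise ValueError(
                f"sampsize={self.sampsize} must lie in [2*min_child, n)"
            )
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.nodesize is not None and self.nodesize <= q:
            raise ValueError(
                f"nodesize={self.nodesize} must exceed the response "
                f"dimension q={q} for stable node covariances"
            )
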