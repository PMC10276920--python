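"""Paired covariate/response container used throughout the package.

Covariates may be numeric or categorical; responses must be numeric with at
least two columns (a covariance matrix of a single response is just a
variance, for which ordinary regression forests suffice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_CATEGORICAL_LEVELS = 64  # level subsets are stored as uint64 bitmasks


@dataclass
class SupervisedSample:
    """A covariate matrix X (n x p) paired with a response matrix Y (n x q).

    Categorical covariate columns are integer-coded against a level set that
    is fixed at construction time; the float matrix ``X`` holds the codes.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Covariates; categorical columns hold level codes 0..L-1 as floats.
    Y : ndarray, shape (n, q)
        Numeric responses, q >= 2.
    is_categorical : ndarray of bool, shape (p,)
        Marks which covariate columns are categorical.
    levels : dict[int, list]
        For each categorical column index, the ordered list of level labels.
    """

    X: np.ndarray
    Y: np.ndarray
    is_categorical: np.ndarray
    levels: dict = field(default_factory=dict)
    x_names: list = field(default_factory=list)
    y_names: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be two-dimensional")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        if self.Y.shape[1] < 2:
            raise ValueError("the response must have q >= 2 columns")
        if np.isnan(self.X).any():
            raise ValueError("missing values in X are not supported")
        if np.isnan(self.Y).any():
            raise ValueError("missing values in Y are not supported")
        self.is_categorical = np.asarray(self.is_categorical, dtype=bool)
        if self.is_categorical.shape != (self.X.shape[1],):
            raise ValueError("is_categorical must have one entry per covariate")
        for j in np.flatnonzero(self.is_categorical):
            lv = self.levels.get(j)
            if lv is None:
                raise ValueError(f"categorical column {j} has no level set")
            if len(lv) > MAX_CATEGORICAL_LEVELS:
                raise ValueError(
                    f"categorical column {j} has {len(lv)} levels; "
                    f"at most {MAX_CATEGORICAL_LEVELS} are supported"
                )
        if not self.x_names:
            self.x_names = [f"X{j + 1}" for j in range(self.X.shape[1])]
        if not self.y_names:
            self.y_names = [f"Y{j + 1}" for j in range(self.Y.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    @classmethod
    def from_frames(cls, Y: pd.DataFrame, X: pd.DataFrame) -> "SupervisedSample":
        """Build a sample from pandas frames, inferring column types.

        Non-numeric X columns (object / category / bool) become categoricals;
        every Y column must be numeric.
        """
        Y = pd.DataFrame(Y)
        X = pd.DataFrame(X)
        if Y.isna().any().any() or X.isna().any().any():
            bad = "Y" if Y.isna().any().any() else "X"
            raise ValueError(f"missing values found in {bad}")
        for c in Y.columns:
            if not pd.api.types.is_numeric_dtype(Y[c]):
                raise ValueError(f"response column {c!r} is not numeric")
        n, p = X.shape
        Xm = np.empty((n, p), dtype=np.float64)
        is_cat = np.zeros(p, dtype=bool)
        levels: dict = {}
        for j, c in enumerate(X.columns):
            col = X[c]
            if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
                Xm[:, j] = col.to_numpy(dtype=np.float64)
            else:
                cats = pd.Categorical(col)
                is_cat[j] = True
                levels[j] = list(cats.categories)
                Xm[:, j] = cats.codes.astype(np.float64)
        return cls(
            X=Xm,
            Y=Y.to_numpy(dtype=np.float64),
            is_categorical=is_cat,
            levels=levels,
            x_names=[str(c) for c in X.columns],
            y_names=[str(c) for c in Y.columns],
        )

    def encode_query(self, X_new: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Encode new covariate rows against the training schema.

        Unseen categorical levels are coded as -1; tree routing sends such
        rows down both children of any node that splits on that column.
        """
        if isinstance(X_new, pd.DataFrame):
            if list(map(str, X_new.columns)) != self.x_names:
                raise ValueError(
                    "query covariate columns do not match the training schema"
                )
            n = len(X_new)
            out = np.empty((n, self.p), dtype=np.float64)
            for j, c in enumerate(X_new.columns):
                if self.is_categorical[j]:
                    cats = pd.Categorical(X_new[c], categories=self.levels[j])
                    out[:, j] = cats.codes.astype(np.float64)  # unseen -> -1
                else:
                    out[:, j] = X_new[c].to_numpy(dtype=np.float64)
        else:
            out = np.asarray(X_new, dtype=np.float64)
            if out.ndim == 1:
                out = out[None, :]
            if out.shape[1] != self.p:
                raise ValueError(
                    f"query has {out.shape[1]} covariates, expected {self.p}"
                )
        if np.isnan(out).any():
            raise ValueError("missing values in query covariates")
        return out

    def subset_columns(self, columns) -> "SupervisedSample":
        """Restrict to a subset of covariate columns (control-model fits)."""
        columns = list(columns)
        levels = {
            k: self.levels[j]
            for k, j in enumerate(columns)
            if j in self.levels
        }
        return SupervisedSample(
            X=self.X[:, columns],
            Y=self.Y,
            is_categorical=self.is_categorical[columns],
            levels=levels,
            x_names=[self.x_names[j] for j in columns],
            y_names=list(self.y_names),
        )

    def with_X(self, X_new: np.ndarray) -> "SupervisedSample":
        """Same schema, different covariate rows (used by permutation tests)."""
        return SupervisedSample(
            X=X_new,
            Y=self.Y,
            is_categorical=self.is_categorical.copy(),
            levels=dict(self.levels),
            x_names=list(self.x_names),
            y_names=list(self.y_names),
        )
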