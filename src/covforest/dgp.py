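"""Synthetic heteroscedastic multivariate-normal generators.

Four data generating processes with known per-observation covariance
matrices Sigma_x, so estimation accuracy can be measured exactly:

* ``dgp1`` - one uniform covariate, Sigma_x = Psi + B (1,x)' (1,x) B'
  (a rank-one quadratic form in x; the linear covariance-regression model).
* ``dgp2`` - same with regressor (1, x + x^2)': a quadratic effect.
* ``dgp3`` - seven standard-normal covariates; a fixed depth-3 decision tree
  with eight leaves assigns each row a base correlation rho, and Sigma_x is
  AR(1) with entries sigma_j sigma_k rho^|j-k| and heterogeneous variances
  sigma_j = 1 + rho j / q.
* ``dgp4`` - standard-normal covariates; compound symmetry with
  rho_i = expit(beta0 + beta' x_i), off-diagonals sigma_j sigma_k rho_i and
  the same variance function.

Responses are drawn as y_i ~ N(0, Sigma_{x_i}).  All randomness flows from
a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._dgp_constants import (
    DGP12_B,
    DGP12_PSI,
    DGP3_LEAF_RHO,
    DGP4_BETA,
    DGP4_BETA0,
)
from .sample import SupervisedSample

__all__ = [
    "SimulatedDataset",
    "dgp1",
    "dgp2",
    "dgp3",
    "dgp4",
    "add_noise_covariates",
]


@dataclass
class SimulatedDataset:
    """Covariates, responses and the true per-row covariance matrices."""

    X: np.ndarray
    Y: np.ndarray
    sigma: np.ndarray  # (n, q, q) true covariances
    name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    def to_sample(self) -> SupervisedSample:
        p = self.X.shape[1]
        return SupervisedSample(
            X=self.X,
            Y=self.Y,
            is_categorical=np.zeros(p, dtype=bool),
        )


def _draw_responses(sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """y_i ~ N(0, sigma_i), one Cholesky per distinct covariance."""
    n, q, _ = sigma.shape
    L = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, q))
    return np.einsum("nij,nj->ni", L, z)


def _ar1_sigma(rho: np.ndarray, q: int) -> np.ndarray:
    """AR(1) covariances with heterogeneous variances sigma_j = 1 + rho j/q."""
    j = np.arange(1, q + 1)
    sd = 1.0 + rho[:, None] * j[None, :] / q  # (n, q)
    lag = np.abs(j[:, None] - j[None, :])  # (q, q)
    corr = rho[:, None, None] ** lag[None, :, :]
    return sd[:, :, None] * sd[:, None, :] * corr


def _cs_sigma(rho: np.ndarray, q: int) -> np.ndarray:
    """Compound-symmetry covariances with the same variance function."""
    j = np.arange(1, q + 1)
    sd = 1.0 + rho[:, None] * j[None, :] / q
    eye = np.eye(q)
    corr = rho[:, None, None] * (1.0 - eye)[None, :, :] + eye[None, :, :]
    return sd[:, :, None] * sd[:, None, :] * corr


def _quadratic_form_dataset(n, Psi, B, seed, transform, name) -> SimulatedDataset:
    Psi = np.asarray(Psi, dtype=float)
    B = np.asarray(B, dtype=float)
    if Psi.shape[0] != Psi.shape[1] or not np.allclose(Psi, Psi.T):
        raise ValueError("Psi must be symmetric")
    if np.linalg.eigvalsh(Psi).min() <= 0:
        raise ValueError("Psi must be positive-definite")
    q = Psi.shape[0]
    if B.shape != (q, 2):
        raise ValueError(f"B must be {q} x 2")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1.0, 1.0, size=n)
    u = np.stack([np.ones(n), transform(x)], axis=1)  # (n, 2)
    Bu = u @ B.T  # (n, q)
    sigma = Psi[None, :, :] + Bu[:, :, None] * Bu[:, None, :]
    Y = _draw_responses(sigma, rng)
    return SimulatedDataset(
        X=x[:, None],
        Y=Y,
        sigma=sigma,
        name=name,
        params={"Psi": Psi, "B": B},
        seed=seed,
    )


def dgp1(n: int, Psi=None, B=None, seed: int | None = None) -> SimulatedDataset:
    """One covariate x ~ U[-1, 1]; Sigma_x = Psi + B (1, x)' (1, x) B'."""
    Psi = DGP12_PSI if Psi is None else Psi
    B = DGP12_B if B is None else B
    return _quadratic_form_dataset(n, Psi, B, seed, lambda x: x, "dgp1")


def dgp2(n: int, Psi=None, B=None, seed: int | None = None) -> SimulatedDataset:
    """As dgp1 with the quadratic regressor (1, x + x^2)'."""
    Psi = DGP12_PSI if Psi is None else Psi
    B = DGP12_B if B is None else B
    return _quadratic_form_dataset(n, Psi, B, seed, lambda x: x + x**2, "dgp2")


def dgp3_leaf(X: np.ndarray) -> np.ndarray:
    """Leaf index (0..7) of each row under the fixed depth-3 tree:
    X1 at the root, X2/X3 at depth two, X4/X5/X6/X7 at depth three."""
    b1 = (X[:, 0] > 0).astype(int)
    b2 = np.where(b1 == 0, X[:, 1] > 0, X[:, 2] > 0).astype(int)
    third = np.select(
        [
            (b1 == 0) & (b2 == 0),
            (b1 == 0) & (b2 == 1),
            (b1 == 1) & (b2 == 0),
        ],
        [X[:, 3], X[:, 4], X[:, 5]],
        default=X[:, 6],
    )
    b3 = (third > 0).astype(int)
    return 4 * b1 + 2 * b2 + b3


def dgp3(n: int, q: int = 5, seed: int | None = None) -> SimulatedDataset:
    """Seven N(0,1) covariates; AR(1) covariance whose base correlation is a
    depth-3 tree function of all seven covariates (eight distinct regimes)."""
    if q < 2:
        raise ValueError("q must be >= 2")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 7))
    rho = DGP3_LEAF_RHO[dgp3_leaf(X)]
    sigma = _ar1_sigma(rho, q)
    Y = _draw_responses(sigma, rng)
    return SimulatedDataset(
        X=X, Y=Y, sigma=sigma, name="dgp3", params={"q": q}, seed=seed
    )


def dgp4(
    n: int, p: int = 3, q: int = 5, seed: int | None = None, beta=None
) -> SimulatedDataset:
    """Standard-normal covariates; compound-symmetry covariance with
    rho_i = expit(beta0 + beta' x_i).

    The default coefficients (2, 1, 0.5, 0, 0, ...) make X1 the strongest
    and X3 the weakest informative covariate; beta = 0 gives a constant
    covariance (a null-hypothesis generator).
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if beta is None:
        beta = np.zeros(p)
        k = min(p, len(DGP4_BETA))
        beta[:k] = DGP4_BETA[:k]
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (p,):
        raise ValueError(f"beta must have length p={p}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    rho = expit(DGP4_BETA0 + X @ beta)
    sigma = _cs_sigma(rho, q)
    Y = _draw_responses(sigma, rng)
    return SimulatedDataset(
        X=X,
        Y=Y,
        sigma=sigma,
        name="dgp4",
        params={"p": p, "q": q, "beta": beta},
        seed=seed,
    )


def add_noise_covariates(
    dataset: SimulatedDataset, k: int, seed: int | None = None
) -> SimulatedDataset:
    """Append k standard-normal covariates independent of everything else;
    the true covariances are unchanged."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return dataset
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((dataset.n, k))
    return SimulatedDataset(
        X=np.hstack([dataset.X, Z]),
        Y=dataset.Y,
        sigma=dataset.sigma,
        name=f"{dataset.name}+noise{k}",
        params={**dataset.params, "noise": k},
        seed=dataset.seed,
    )
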