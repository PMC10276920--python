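"""Accuracy metrics comparing estimated and true covariance collections."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["AccuracyReport", "mae_cor", "mae_sd", "stein_loss", "evaluate"]


def _as_stack(mats) -> np.ndarray:
    """Coerce a list of q x q matrices (or CovarianceEstimates) to (n, q, q)."""
    arr = [getattr(m, "matrix", m) for m in mats]
    return np.asarray(arr, dtype=float)


def _cor_from_cov(S: np.ndarray) -> np.ndarray:
    """Correlation matrices from a (n, q, q) covariance stack; zero-variance
    coordinates yield zero correlations (with a warning)."""
    sd = np.sqrt(np.einsum("nii->ni", S))
    if np.any(sd == 0):
        warnings.warn(
            "zero variance encountered; its correlations are set to 0",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        C = S / (sd[:, :, None] * sd[:, None, :])
    C = np.where(np.isfinite(C), C, 0.0)
    return C


def mae_cor(est, truth) -> float:
    """Mean absolute error between estimated and true correlations, averaged
    over the strict upper triangle and all observations."""
    E = _as_stack(est)
    T = _as_stack(truth)
    if E.shape != T.shape:
        raise ValueError(f"incompatible shapes {E.shape} and {T.shape}")
    q = E.shape[1]
    if q < 2:
        raise ValueError("correlation MAE needs q >= 2")
    iu = np.triu_indices(q, k=1)
    Ce = _cor_from_cov(E)[:, iu[0], iu[1]]
    Ct = _cor_from_cov(T)[:, iu[0], iu[1]]
    return float(np.abs(Ce - Ct).mean())


def mae_sd(est, truth) -> float:
    """Normalized mean absolute error of standard deviations:
    mean over observations and coordinates of |sd_hat - sd| / sd."""
    E = _as_stack(est)
    T = _as_stack(truth)
    if E.shape != T.shape:
        raise ValueError(f"incompatible shapes {E.shape} and {T.shape}")
    se = np.sqrt(np.einsum("nii->ni", E))
    st = np.sqrt(np.einsum("nii->ni", T))
    if np.any(st <= 0):
        raise ValueError("true standard deviations must be strictly positive")
    return float((np.abs(se - st) / st).mean())


def stein_loss(est: np.ndarray, truth: np.ndarray) -> float:
    """Stein's loss tr(E T^-1) - log det(E T^-1) - q: the Gaussian
    Kullback-Leibler divergence (x2) of N(0, est) from N(0, truth).

    Zero iff the matrices are equal; requires both positive-definite.
    """
    E = np.asarray(getattr(est, "matrix", est), dtype=float)
    T = np.asarray(getattr(truth, "matrix", truth), dtype=float)
    q = E.shape[0]
    try:
        Lt = np.linalg.cholesky(T)
    except np.linalg.LinAlgError as err:
        raise ValueError("true covariance is not positive-definite") from err
    M = np.linalg.solve(T, E)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("estimate is singular or not positive-definite")
    _ = Lt
    return float(np.trace(M) - logdet - q)


@dataclass
class AccuracyReport:
    """Summary of estimation accuracy on a labelled test set."""

    mae_cor: float
    mae_sd: float
    mean_stein: float
    n_test: int
    q: int


def evaluate(est, truth, stein: bool = True) -> AccuracyReport:
    E = _as_stack(est)
    T = _as_stack(truth)
    mean_stein = (
        float(np.mean([stein_loss(e, t) for e, t in zip(E, T)]))
        if stein
        else float("nan")
    )
    return AccuracyReport(
        mae_cor=mae_cor(E, T),
        mae_sd=mae_sd(E, T),
        mean_stein=mean_stein,
        n_test=E.shape[0],
        q=E.shape[1],
    )
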