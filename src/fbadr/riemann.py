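"""Riemannian tangent-space features on SPD spatial covariance matrices.

An epoch ``X`` (channels x times, zero-mean after filtering) is summarized
by its sample covariance ``C = X X^T / (N-1)``, shrunk toward a scaled
identity with the oracle-approximating-shrinkage (OAS) estimator so every
matrix is strictly positive definite.  Matrices are then projected to the
tangent space at a reference point ``C_ref`` — the log-Euclidean mean of
the training covariances — via

    S = C_ref^{1/2} logm( C_ref^{-1/2} C C_ref^{-1/2} ) C_ref^{1/2}

and flattened row-major to a length ``K^2`` vector (961 for K=31), where
Euclidean classifiers apply.  ``tangent_retract`` is the exact inverse
(exponential map back to the manifold).
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import BandedEpochs

__all__ = [
    "covariance",
    "oas_regularize",
    "logm_spd",
    "expm_sym",
    "sqrtm_spd",
    "invsqrtm_spd",
    "log_euclidean_mean",
    "tangent_project",
    "tangent_retract",
    "band_covariances",
    "fit_references",
    "extract_features",
]

#: relative eigenvalue floor applied before matrix logarithms
EIG_FLOOR = 1e-10


def covariance(epoch: np.ndarray) -> np.ndarray:
    """Sample covariance ``X X^T / (N-1)`` of a channels-x-times epoch."""
    x = np.asarray(epoch, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("epoch must be 2-D (channels x times)")
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 time points")
    c = x @ x.T / (n - 1)
    return (c + c.T) / 2.0


def oas_regularize(cov: np.ndarray, n_obs: int) -> np.ndarray:
    """OAS shrinkage toward the scaled identity ``mu I``, ``mu = tr(C)/K``.

    Uses the closed-form shrinkage intensity of Chen et al.; the result is
    ``(1-rho) C + rho mu I`` with ``rho`` clipped to [0, 1], strictly
    positive definite whenever ``tr(C) > 0``.
    """
    c = np.asarray(cov, dtype=np.float64)
    k = c.shape[0]
    if c.shape != (k, k) or not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("covariance must be square symmetric")
    tr = np.trace(c)
    if tr <= 0:
        warnings.warn("zero-trace covariance: returning identity floor")
        return np.eye(k) * max(EIG_FLOOR, 1.0)
    mu = tr / k
    tr_c2 = float(np.sum(c * c))  # trace(C @ C) for symmetric C
    num = (1.0 - 2.0 / k) * tr_c2 + tr**2
    den = (n_obs + 1.0 - 2.0 / k) * (tr_c2 - tr**2 / k)
    rho = 1.0 if den <= 0 else min(num / den, 1.0)
    out = (1.0 - rho) * c + rho * mu * np.eye(k)
    return (out + out.T) / 2.0


def _eigh_checked(spd: np.ndarray, require_spd: bool) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(spd, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")
    w, v = np.linalg.eigh((s + s.T) / 2.0)
    if require_spd:
        if w[-1] <= 0 or w[0] <= -1e-8 * w[-1]:
            raise ValueError("matrix is not positive definite")
        w = np.maximum(w, EIG_FLOOR * w[-1])
    return w, v


def _apply_spectral(spd: np.ndarray, fn, require_spd: bool) -> np.ndarray:
    w, v = _eigh_checked(spd, require_spd)
    out = (v * fn(w)) @ v.T
    return (out + out.T) / 2.0


def logm_spd(spd: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (symmetric result)."""
    return _apply_spectral(spd, np.log, require_spd=True)


def expm_sym(sym: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (SPD result)."""
    return _apply_spectral(sym, np.exp, require_spd=False)


def sqrtm_spd(spd: np.ndarray) -> np.ndarray:
    return _apply_spectral(spd, np.sqrt, require_spd=True)


def invsqrtm_spd(spd: np.ndarray) -> np.ndarray:
    return _apply_spectral(spd, lambda w: 1.0 / np.sqrt(w), require_spd=True)


def log_euclidean_mean(cov_list) -> np.ndarray:
    """Log-Euclidean mean ``expm( mean_i logm(C_i) )`` of SPD matrices."""
    covs = list(cov_list)
    if not covs:
        raise ValueError("empty covariance list")
    logs = np.stack([logm_spd(c) for c in covs])
    return expm_sym(logs.mean(axis=0))


def tangent_project(cov: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Project an SPD matrix to the tangent space at ``reference``."""
    cov = np.asarray(cov, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if cov.shape != reference.shape:
        raise ValueError("dimension mismatch between covariance and reference")
    r_half = sqrtm_spd(reference)
    r_inv_half = invsqrtm_spd(reference)
    inner = logm_spd(r_inv_half @ cov @ r_inv_half)
    out = r_half @ inner @ r_half
    return (out + out.T) / 2.0


def tangent_retract(tangent: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Exponential map from the tangent space back to the manifold."""
    tangent = np.asarray(tangent, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if tangent.shape != reference.shape:
        raise ValueError("dimension mismatch between tangent and reference")
    r_half = sqrtm_spd(reference)
    r_inv_half = invsqrtm_spd(reference)
    inner = expm_sym(r_inv_half @ ((tangent + tangent.T) / 2.0) @ r_inv_half)
    out = r_half @ inner @ r_half
    return (out + out.T) / 2.0


def band_covariances(banded: BandedEpochs) -> dict[int, np.ndarray]:
    """OAS-regularized covariance per epoch, per band: band -> (n, K, K)."""
    out: dict[int, np.ndarray] = {}
    for b in banded.band_indices:
        es = banded.bands[b]
        n_obs = es.n_times
        out[b] = np.stack([oas_regularize(covariance(e), n_obs) for e in es.epochs])
    return out


def fit_references(cov_dict: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    """Per-band log-Euclidean mean reference from *training* covariances."""
    return {b: log_euclidean_mean(list(covs)) for b, covs in cov_dict.items()}


def extract_features(
    cov_dict: dict[int, np.ndarray], references: dict[int, np.ndarray]
) -> dict[int, np.ndarray]:
    """Flattened tangent features per band: band -> (n, K*K).

    References must have been fitted on training data only; they are
    reused unchanged for validation and test covariances.
    """
    out: dict[int, np.ndarray] = {}
    for b, covs in cov_dict.items():
        if b not in references:
            raise ValueError(f"missing reference for band {b}")
        ref = references[b]
        r_half = sqrtm_spd(ref)
        r_inv_half = invsqrtm_spd(ref)
        feats = np.empty((covs.shape[0], ref.shape[0] ** 2))
        for i, c in enumerate(covs):
            inner = logm_spd(r_inv_half @ c @ r_inv_half)
            s = r_half @ inner @ r_half
            feats[i] = ((s + s.T) / 2.0).reshape(-1)
        out[b] = feats
    return out
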