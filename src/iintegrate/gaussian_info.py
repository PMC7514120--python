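"""Gaussian information-theoretic primitives on covariance matrices.

Everything here operates purely on covariance matrices of jointly Gaussian
variables: differential entropy, mutual information and conditional mutual
information all reduce to log-determinants, and conditioning reduces to the
Schur complement (partial covariance).  All information quantities are in
nats (natural logarithm).

Numerical conventions
---------------------
* Log-determinants are computed from a Cholesky factorisation of the
  symmetric matrix, never from a raw determinant.
* Positive definiteness is required where differential entropy or an MI is
  undefined otherwise; a matrix whose smallest eigenvalue is below
  ``1e-10`` times its largest is treated as degenerate and raises
  :class:`~iintegrate.errors.DegenerateModelError` instead of being
  regularised — degeneracy (e.g. perfectly correlated noise) is surfaced,
  not masked.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import DegenerateModelError, UsageError

__all__ = [
    "LOG_2PI_E",
    "check_covariance",
    "logdet_pd",
    "partial_covariance",
    "gaussian_entropy",
    "gaussian_mi",
    "conditional_mi",
]

#: log(2·π·e), the additive constant of Gaussian differential entropy per dim.
LOG_2PI_E = float(np.log(2.0 * np.pi * np.e))

#: Relative eigenvalue tolerance below which a covariance is degenerate.
PD_RTOL = 1e-10

#: Absolute symmetry / PSD slack for validating covariance inputs.
SYM_ATOL = 1e-10


def check_covariance(sigma: np.ndarray, name: str = "sigma") -> np.ndarray:
    """Validate a covariance matrix: square, symmetric, PSD within tolerance.

    Returns the symmetrised matrix as a float array.  Raises
    :class:`UsageError` for shape/symmetry violations and
    :class:`DegenerateModelError` for matrices with eigenvalues below
    ``-1e-10``.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise UsageError(f"{name} must be a square matrix, got shape {sigma.shape}")
    scale = max(1.0, float(np.abs(sigma).max()))
    if np.abs(sigma - sigma.T).max() > SYM_ATOL * scale:
        raise UsageError(f"{name} is not symmetric within tolerance")
    sigma = 0.5 * (sigma + sigma.T)
    eigs = np.linalg.eigvalsh(sigma)
    if eigs[0] < -SYM_ATOL * scale:
        raise DegenerateModelError(
            f"{name} is not positive semi-definite (min eigenvalue {eigs[0]:.3e})"
        )
    return sigma


def _cho_pd(sigma: np.ndarray, name: str):
    """Cholesky factor of a strictly PD symmetric matrix, or raise."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise UsageError(f"{name} must be square, got shape {sigma.shape}")
    # Fast path: attempt Cholesky; fall back to an eigenvalue diagnosis so the
    # error message names the relative conditioning, not just "not PD".
    try:
        c, low = cho_factor(0.5 * (sigma + sigma.T), lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        eigs = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))
        raise DegenerateModelError(
            f"{name} is not positive definite "
            f"(eigenvalue range [{eigs[0]:.3e}, {eigs[-1]:.3e}])"
        ) from exc
    diag = np.diag(c)
    # Cholesky succeeds for some barely-indefinite-but-rounded matrices; apply
    # the relative eigenvalue policy through the factor's diagonal.
    if diag.min() ** 2 <= PD_RTOL * diag.max() ** 2:
        eigs = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))
        if eigs[0] <= PD_RTOL * max(eigs[-1], 0.0):
            raise DegenerateModelError(
                f"{name} is numerically singular "
                f"(eigenvalue range [{eigs[0]:.3e}, {eigs[-1]:.3e}])"
            )
    return (c, low)


def logdet_pd(sigma: np.ndarray, name: str = "sigma") -> float:
    """log det of a symmetric positive definite matrix via Cholesky."""
    c, _ = _cho_pd(sigma, name)
    return float(2.0 * np.sum(np.log(np.diag(c))))


def partial_covariance(
    sigma_x: np.ndarray, sigma_xy: np.ndarray, sigma_y: np.ndarray, *,
    name_y: str = "sigma_y",
) -> np.ndarray:
    """Conditional covariance Σ(X|Y) = Σ(X) − Σ(X,Y) Σ(Y)⁻¹ Σ(Y,X).

    ``sigma_xy`` is the cross-covariance Cov(X, Y) with shape
    ``(dim X, dim Y)``.  ``sigma_y`` must be positive definite; a singular
    conditioning block raises :class:`DegenerateModelError` naming it.
    """
    sigma_x = np.asarray(sigma_x, dtype=float)
    sigma_xy = np.atleast_2d(np.asarray(sigma_xy, dtype=float))
    sigma_y = np.asarray(sigma_y, dtype=float)
    if sigma_xy.shape != (sigma_x.shape[0], sigma_y.shape[0]):
        raise UsageError(
            f"cross-covariance shape {sigma_xy.shape} not conformable with "
            f"Σ(X) {sigma_x.shape} and Σ(Y) {sigma_y.shape}"
        )
    cf = _cho_pd(sigma_y, name_y)
    out = sigma_x - sigma_xy @ cho_solve(cf, sigma_xy.T, check_finite=False)
    return 0.5 * (out + out.T)


def gaussian_entropy(sigma: np.ndarray, name: str = "sigma") -> float:
    """Differential entropy ½ log det Σ + (n/2) log 2πe of a Gaussian, nats.

    Can be negative (differential entropy has no non-negativity guarantee).
    """
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    n = sigma.shape[0]
    return 0.5 * logdet_pd(sigma, name) + 0.5 * n * LOG_2PI_E


def gaussian_mi(sigma_x: np.ndarray, sigma_x_given_y: np.ndarray) -> float:
    """Mutual information I(X;Y) = ½ log(det Σ(X) / det Σ(X|Y)), nats.

    Takes the marginal covariance of X and the conditional covariance of X
    given Y (e.g. from :func:`partial_covariance`).  Non-negative up to
    round-off for valid inputs.
    """
    sigma_x = np.atleast_2d(np.asarray(sigma_x, dtype=float))
    sigma_x_given_y = np.atleast_2d(np.asarray(sigma_x_given_y, dtype=float))
    if sigma_x.shape != sigma_x_given_y.shape:
        raise UsageError("Σ(X) and Σ(X|Y) must have the same shape")
    return 0.5 * (logdet_pd(sigma_x, "sigma_x")
                  - logdet_pd(sigma_x_given_y, "sigma_x_given_y"))


def conditional_mi(joint, target_idx, source_idx, conditioning_idx=()) -> float:
    """Conditional mutual information I(source; target | conditioning), nats.

    ``joint`` is the covariance of the full Gaussian vector; the three index
    sequences select disjoint sub-blocks.  An empty conditioning set reduces
    to the plain mutual information between the two marginal blocks.
    """
    joint = np.asarray(joint, dtype=float)
    t = np.asarray(list(target_idx), dtype=int)
    s = np.asarray(list(source_idx), dtype=int)
    z = np.asarray(list(conditioning_idx), dtype=int)
    if t.size == 0 or s.size == 0:
        raise UsageError("target and source index sets must be non-empty")
    all_idx = np.concatenate([t, s, z])
    if len(np.unique(all_idx)) != all_idx.size:
        raise UsageError("target, source and conditioning index sets must be disjoint")
    if all_idx.min() < 0 or all_idx.max() >= joint.shape[0]:
        raise UsageError("index out of range for the joint covariance")

    sz = np.concatenate([s, z])
    # Σ(T|Z) and Σ(T|S,Z) via two Schur complements.
    if z.size:
        sigma_t_given_z = partial_covariance(
            joint[np.ix_(t, t)], joint[np.ix_(t, z)], joint[np.ix_(z, z)],
            name_y="conditioning block",
        )
    else:
        sigma_t_given_z = joint[np.ix_(t, t)]
    sigma_t_given_sz = partial_covariance(
        joint[np.ix_(t, t)], joint[np.ix_(t, sz)], joint[np.ix_(sz, sz)],
        name_y="source+conditioning block",
    )
    return gaussian_mi(sigma_t_given_z, sigma_t_given_sz)
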