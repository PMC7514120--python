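"""First-order vector autoregressive systems and their stationary statistics.

A system ``X_{t+1} = A X_t + ε_t`` with white Gaussian noise
``ε_t ~ N(0, Σ(ε))`` is stable (and then stationary) iff the spectral radius
of the coupling matrix A is strictly below 1.  Its stationary covariance
solves the discrete-time Lyapunov equation ``Σ = A Σ Aᵀ + Σ(ε)`` and the
lag-τ covariance is ``Σ(X_{t−τ}, X_t) = Σ (Aᵀ)^τ``.  All integrated
information measures in this package consume the resulting
:class:`StationaryGaussianModel`: the pair (Σ(X), Σ(X_{t−τ}, X_t)) plus the
lag, from which every required joint, marginal and conditional covariance
follows by block extraction and Schur complements.

A trajectory simulator is included purely as a numerical oracle for the
analytic covariances; nothing in the package estimates anything from
samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .errors import StationarityError, UsageError
from .gaussian_info import check_covariance, partial_covariance

__all__ = [
    "ARSystem",
    "StationaryGaussianModel",
    "spectral_radius",
    "normalize_spectral_radius",
    "stationary_covariance",
    "lagged_covariance",
    "build_model",
    "marginalize",
    "simulate",
    "load_system",
]

#: Max ∞-norm residual allowed in ‖Σ − AΣAᵀ − Σ(ε)‖ relative to the noise scale.
LYAPUNOV_RTOL = 1e-10

#: Steps discarded before a simulated trajectory is recorded.  The initial
#: state is drawn from the stationary distribution, so this is belt-and-braces.
BURN_IN = 1000


def spectral_radius(A: np.ndarray) -> float:
    """Largest absolute eigenvalue of a square matrix."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise UsageError(f"coupling matrix must be square, got shape {A.shape}")
    return float(np.abs(np.linalg.eigvals(A)).max())


def normalize_spectral_radius(A: np.ndarray, target: float) -> np.ndarray:
    """Rescale A so its spectral radius equals ``target`` exactly.

    Scale-invariant: normalising 2A gives the same matrix as normalising A.
    """
    if not 0.0 < target < 1.0:
        raise UsageError(f"target spectral radius must be in (0, 1), got {target}")
    rho = spectral_radius(A)
    if rho == 0.0:
        raise UsageError("cannot normalise a matrix with zero spectral radius")
    return np.asarray(A, dtype=float) * (target / rho)


@dataclass(frozen=True)
class ARSystem:
    """An AR(1) system: coupling matrix A and noise covariance Σ(ε)."""

    A: np.ndarray
    sigma_eps: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise UsageError(f"coupling matrix must be square, got shape {A.shape}")
        sigma_eps = check_covariance(self.sigma_eps, "sigma_eps")
        if sigma_eps.shape != A.shape:
            raise UsageError("A and sigma_eps must have matching dimensions")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "sigma_eps", sigma_eps)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def spectral_radius(self) -> float:
        return spectral_radius(self.A)

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


def stationary_covariance(sys: ARSystem) -> np.ndarray:
    """Solve Σ = A Σ Aᵀ + Σ(ε) for the stationary covariance.

    Raises :class:`StationarityError` (naming the spectral radius) for
    unstable systems.  The returned matrix is symmetrised and satisfies the
    Lyapunov residual contract to 1e-10 relative to the noise scale.
    """
    rho = sys.spectral_radius
    if rho >= 1.0:
        raise StationarityError(
            f"system is not stationary: spectral radius {rho:.6g} ≥ 1"
        )
    sigma = solve_discrete_lyapunov(sys.A, sys.sigma_eps)
    sigma = 0.5 * (sigma + sigma.T)
    scale = max(1.0, float(np.abs(sys.sigma_eps).max()), float(np.abs(sigma).max()))
    resid = np.abs(sigma - sys.A @ sigma @ sys.A.T - sys.sigma_eps).max()
    if resid > LYAPUNOV_RTOL * scale:
        raise StationarityError(
            f"Lyapunov solve residual {resid:.3e} exceeds tolerance "
            f"(spectral radius {rho:.6g})"
        )
    return sigma


def lagged_covariance(sigma_x: np.ndarray, A: np.ndarray, tau: int = 1) -> np.ndarray:
    """Lagged covariance Σ(X_{t−τ}, X_t) = Σ(X) (Aᵀ)^τ."""
    if int(tau) != tau or tau < 1:
        raise UsageError(f"lag tau must be a positive integer, got {tau}")
    sigma_x = np.asarray(sigma_x, dtype=float)
    A = np.asarray(A, dtype=float)
    return sigma_x @ np.linalg.matrix_power(A.T, int(tau))


@dataclass(frozen=True)
class StationaryGaussianModel:
    """Stationary joint Gaussian statistics of a process at lag τ.

    ``sigma_x`` is the (stationary, hence time-invariant) covariance of the
    state, ``sigma_lag`` the cross-covariance Σ(X_{t−τ}, X_t).  Variable
    ``i`` of the past state has joint index ``i``; variable ``i`` of the
    present state has joint index ``n + i``.
    """

    sigma_x: np.ndarray
    sigma_lag: np.ndarray
    tau: int = 1

    def __post_init__(self):
        sigma_x = check_covariance(self.sigma_x, "sigma_x")
        sigma_lag = np.asarray(self.sigma_lag, dtype=float)
        if sigma_lag.shape != sigma_x.shape:
            raise UsageError("sigma_lag must match sigma_x in shape")
        if int(self.tau) < 1:
            raise UsageError(f"lag tau must be ≥ 1, got {self.tau}")
        object.__setattr__(self, "sigma_x", sigma_x)
        object.__setattr__(self, "sigma_lag", sigma_lag)
        object.__setattr__(self, "tau", int(self.tau))

    @property
    def n(self) -> int:
        return self.sigma_x.shape[0]

    @property
    def joint(self) -> np.ndarray:
        """2n×2n covariance of (X_{t−τ}, X_t); past block first."""
        return np.block([[self.sigma_x, self.sigma_lag],
                         [self.sigma_lag.T, self.sigma_x]])

    def sigma_present_given_past(self) -> np.ndarray:
        """Σ(X_t | X_{t−τ}); equals Σ(ε) for an AR(1) at τ=1."""
        return partial_covariance(self.sigma_x, self.sigma_lag.T, self.sigma_x,
                                  name_y="sigma_x (past)")

    def sigma_past_given_present(self) -> np.ndarray:
        """Σ(X_{t−τ} | X_t)."""
        return partial_covariance(self.sigma_x, self.sigma_lag, self.sigma_x,
                                  name_y="sigma_x (present)")

    def effective_coupling(self) -> np.ndarray:
        """Lag-τ regression matrix Σ(X_t, X_{t−τ}) Σ(X)⁻¹.

        For an AR(1) at τ=1 this recovers the coupling matrix A exactly,
        since Σ_lag = Σ Aᵀ.  It is also well-defined for time-reversed or
        marginalised models that do not come from an explicit coupling.
        """
        return np.linalg.solve(self.sigma_x, self.sigma_lag).T

    def marginalize(self, part) -> "StationaryGaussianModel":
        """Sub-model on an index set: block extraction of Σ and Σ_lag."""
        idx = np.asarray(list(part), dtype=int)
        if idx.size == 0:
            raise UsageError("cannot marginalize onto an empty part")
        if len(np.unique(idx)) != idx.size:
            raise UsageError("part contains repeated indices")
        if idx.min() < 0 or idx.max() >= self.n:
            raise UsageError(f"part {list(part)} out of range for n={self.n}")
        return StationaryGaussianModel(
            sigma_x=self.sigma_x[np.ix_(idx, idx)],
            sigma_lag=self.sigma_lag[np.ix_(idx, idx)],
            tau=self.tau,
        )

    def time_reversed(self) -> "StationaryGaussianModel":
        """Model of the time-reversed process: the lagged covariance block
        transposes, the stationary covariance is unchanged."""
        return StationaryGaussianModel(self.sigma_x, self.sigma_lag.T, self.tau)


def build_model(sys: ARSystem, tau: int = 1) -> StationaryGaussianModel:
    """Stationary Gaussian model of an AR(1) system at lag τ."""
    sigma = stationary_covariance(sys)
    return StationaryGaussianModel(
        sigma_x=sigma,
        sigma_lag=lagged_covariance(sigma, sys.A, tau),
        tau=tau,
    )


def simulate(sys: ARSystem, steps: int, seed, burn_in: int = BURN_IN) -> np.ndarray:
    """Simulate a trajectory; rows are time steps, columns variables.

    The initial state is drawn from the stationary distribution and
    ``burn_in`` further steps are discarded, so the recorded trajectory is
    stationary from the first row.  Reproducible given ``seed`` (an int or a
    ``numpy.random.Generator``).
    """
    if steps < 1:
        raise UsageError(f"steps must be ≥ 1, got {steps}")
    sigma = stationary_covariance(sys)  # raises for unstable systems
    rng = np.random.default_rng(seed)
    n = sys.n
    chol_sigma = np.linalg.cholesky(sigma)
    chol_eps = np.linalg.cholesky(sys.sigma_eps)
    x = chol_sigma @ rng.standard_normal(n)
    noise = rng.standard_normal((burn_in + steps, n)) @ chol_eps.T
    out = np.empty((steps, n))
    A = sys.A
    for t in range(burn_in):
        x = A @ x + noise[t]
    for t in range(steps):
        x = A @ x + noise[burn_in + t]
        out[t] = x
    return out


def marginalize(model: StationaryGaussianModel, part) -> StationaryGaussianModel:
    """Functional alias for :meth:`StationaryGaussianModel.marginalize`."""
    return model.marginalize(part)


def load_system(path) -> ARSystem:
    """Read an AR system from a JSON model file.

    Accepted forms::

        {"A": [[...]], "noise_cov": [[...]]}
        {"A": [[...]], "noise_corr_c": 0.2}

    The second expands to an equicorrelated noise covariance with unit
    diagonal and constant off-diagonal c.
    """
    with open(path) as fh:
        spec = json.load(fh)
    if "A" not in spec:
        raise UsageError(f"model file {path} lacks an 'A' entry")
    A = np.asarray(spec["A"], dtype=float)
    if "noise_cov" in spec:
        sigma_eps = np.asarray(spec["noise_cov"], dtype=float)
    elif "noise_corr_c" in spec:
        c = float(spec["noise_corr_c"])
        n = A.shape[0]
        sigma_eps = np.full((n, n), c)
        np.fill_diagonal(sigma_eps, 1.0)
    else:
        raise UsageError(
            f"model file {path} needs either 'noise_cov' or 'noise_corr_c'"
        )
    return ARSystem(A=A, sigma_eps=sigma_eps)
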