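"""The six integrated-information / dynamical-complexity measures, plus the
two control quantities (time-delayed mutual information and average absolute
correlation).

Every measure comes in two forms: a per-partition *effective information*
``effective_info_*(model, partition)`` and a partition-scanned measure
returning a :class:`MeasureResult` (minimised over even bipartitions by
default, via :func:`iintegrate.partitions.find_mip`).

All values are in nats except the average absolute correlation, which is
dimensionless.  Throughout, ``model`` is a
:class:`~iintegrate.ar_model.StationaryGaussianModel` holding the stationary
covariance Σ(X), the lag-τ cross-covariance Σ(X_{t−τ}, X_t) and the lag.

The measures
------------
Φ (whole-minus-sum)
    TDMI of the whole minus the sum of each part's own TDMI.  Interpretable
    as net synergy; can be negative when redundancy dominates.
Φ̃ (stochastic interaction)
    Increase in conditional entropy of the past given the present when the
    system is split.  Non-negative; equals Φ plus the instantaneous
    multi-information across the parts, and can exceed TDMI.
ψ (integrated synergy)
    TDMI minus the union information of the parts' pasts about the whole
    present, under the minimum-mutual-information partial information
    decomposition, where the union information collapses to
    max_k I(M^k_{t−τ}; X_t) for Gaussians.
Φ* (decoder-based)
    TDMI minus the mismatched-decoding information I*, the information
    extractable when decoding the past with a partition-factorised model of
    the transition.  I* = max_β Ĩ(β) with Ĩ concave in β.
Φ_G (geometric)
    KL divergence from the full process distribution to its M-projection on
    the manifold of models with cross-partition causal links severed
    (instantaneous correlations between parts remain allowed).
CD (causal density)
    Average pairwise conditional transfer entropy between parts; vanishes
    both for fully segregated and fully synchronised dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from .ar_model import StationaryGaussianModel
from .errors import DegenerateModelError, SolverError, UsageError
from .gaussian_info import (
    conditional_mi,
    gaussian_entropy,
    gaussian_mi,
    logdet_pd,
    partial_covariance,
)
from .partitions import MIPResult, Partition, find_mip

__all__ = [
    "MeasureResult",
    "MismatchedDecodingState",
    "GeometricProjectionState",
    "tdmi",
    "avg_abs_correlation",
    "effective_info_phi",
    "phi_wms",
    "effective_info_phi_tilde",
    "phi_tilde",
    "multi_information",
    "union_information_mmi",
    "effective_info_psi",
    "psi",
    "i_tilde_beta",
    "effective_info_phi_star",
    "phi_star",
    "phi_g",
    "phi_g_measure",
    "transfer_entropy",
    "causal_density",
    "cd_measure",
    "compute_all",
    "MEASURE_NAMES",
]


@dataclass(frozen=True)
class MeasureResult:
    """A computed measure: name, value (nats; Σ̄ dimensionless), the
    minimising partition for partition-scanned measures, and solver
    diagnostics (β*, iteration counts, constraint residuals, ...)."""

    name: str
    value: float
    partition: Optional[Partition] = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Control quantities
# ---------------------------------------------------------------------------

def tdmi(model: StationaryGaussianModel) -> float:
    """Time-delayed mutual information I(X_{t−τ}; X_t) of the whole system."""
    return gaussian_mi(model.sigma_x, model.sigma_present_given_past())


def avg_abs_correlation(model: StationaryGaussianModel) -> float:
    """Mean |corr_ij| over the off-diagonal entries of the stationary
    correlation matrix; the Σ̄ control quantity, in [0, 1]."""
    sigma = model.sigma_x
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    n = model.n
    if n < 2:
        return 0.0
    off = np.abs(corr[~np.eye(n, dtype=bool)])
    return float(off.mean())


# ---------------------------------------------------------------------------
# Whole-minus-sum Φ and stochastic interaction Φ̃
# ---------------------------------------------------------------------------

def effective_info_phi(model: StationaryGaussianModel, partition: Partition) -> float:
    """φ(P) = I(X_{t−τ};X_t) − Σ_k I(M^k_{t−τ};M^k_t).  May be negative."""
    value = tdmi(model)
    for p in partition.parts:
        value -= tdmi(model.marginalize(p))
    return value


def phi_wms(model: StationaryGaussianModel, scheme: str = "even") -> MeasureResult:
    """Whole-minus-sum integrated information Φ: φ at the MIP."""
    mip = find_mip(model, effective_info_phi, scheme=scheme)
    return MeasureResult("phi", mip.value, mip.partition,
                         {"candidates_evaluated": mip.candidates_evaluated})


def effective_info_phi_tilde(model: StationaryGaussianModel,
                             partition: Partition) -> float:
    """φ̃(P) = Σ_k H(M^k_{t−τ}|M^k_t) − H(X_{t−τ}|X_t) ≥ 0."""
    n = model.n
    value = -(0.5 * logdet_pd(model.sigma_past_given_present(),
                              "sigma_past_given_present"))
    for p in partition.parts:
        sub = model.marginalize(p)
        value += 0.5 * logdet_pd(sub.sigma_past_given_present(),
                                 f"part {p} past|present")
    # the (n/2)·log 2πe terms cancel between whole and parts
    return value


def phi_tilde(model: StationaryGaussianModel, scheme: str = "even") -> MeasureResult:
    """Integrated stochastic interaction Φ̃: φ̃ at the MIP."""
    mip = find_mip(model, effective_info_phi_tilde, scheme=scheme)
    return MeasureResult("phi_tilde", mip.value, mip.partition,
                         {"candidates_evaluated": mip.candidates_evaluated})


def multi_information(model: StationaryGaussianModel, partition: Partition) -> float:
    """Instantaneous multi-information across parts,
    Σ_k H(M^k_t) − H(X_t) ≥ 0.  Links Φ and Φ̃: φ̃ = φ + multi-information."""
    value = -(0.5 * logdet_pd(model.sigma_x, "sigma_x"))
    for p in partition.parts:
        idx = np.asarray(p, dtype=int)
        value += 0.5 * logdet_pd(model.sigma_x[np.ix_(idx, idx)], f"part {p}")
    return value


# ---------------------------------------------------------------------------
# Integrated synergy ψ (MMI partial information decomposition)
# ---------------------------------------------------------------------------

def union_information_mmi(model: StationaryGaussianModel,
                          partition: Partition) -> float:
    """Union information of the parts' pasts about the whole present under
    the minimum-mutual-information PID: max_k I(M^k_{t−τ}; X_t)."""
    best = -np.inf
    for p in partition.parts:
        idx = np.asarray(p, dtype=int)
        sigma_part = model.sigma_x[np.ix_(idx, idx)]
        cross = model.sigma_lag[idx, :]  # Cov(M^k_{t−τ}, X_t)
        cond = partial_covariance(sigma_part, cross, model.sigma_x,
                                  name_y="sigma_x (present)")
        best = max(best, gaussian_mi(sigma_part, cond))
    return best


def effective_info_psi(model: StationaryGaussianModel,
                       partition: Partition) -> float:
    """ψ(P) = TDMI − I_∪(P) ≥ 0: predictive information no single part
    carries alone."""
    return tdmi(model) - union_information_mmi(model, partition)


def psi(model: StationaryGaussianModel, scheme: str = "even") -> MeasureResult:
    """Integrated synergy ψ: min over the scheme of TDMI − I_∪ (equivalently
    TDMI minus the best union information any partition achieves)."""
    mip = find_mip(model, effective_info_psi, scheme=scheme)
    return MeasureResult("psi", mip.value, mip.partition,
                         {"candidates_evaluated": mip.candidates_evaluated})


# ---------------------------------------------------------------------------
# Decoder-based Φ* (mismatched decoding)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MismatchedDecodingState:
    """One evaluation of the Gaussian mismatched-decoding curve Ĩ(β).

    The restricted decoder q(X_t|X_{t−τ}) = ∏_k p(M^k_t|M^k_{t−τ}) is
    Gaussian with block-diagonal regression ``a_tilde`` and block-diagonal
    conditional covariance ``sigma_q``.  ``precision_sum`` is
    Σ(X)⁻¹ + β Ãᵀ Σ_q⁻¹ Ã, the posterior precision of the past under the
    β-tilted decoder; ``mismatch_cov`` is E[(X_t − Ã X_{t−τ})(·)ᵀ], the
    second moment of the decoder's residual under the true model.
    Ĩ(β) is concave in β and Ĩ(β) ≤ TDMI for all β ≥ 0, with equality at
    β = 1 when the decoder matches the true transition.
    """

    beta: float
    i_tilde: float
    a_tilde: np.ndarray
    sigma_q: np.ndarray
    precision_sum: np.ndarray
    mismatch_cov: np.ndarray


class _MismatchedDecoder:
    """Partition-dependent precomputation for evaluating Ĩ(β) cheaply.

    Derivation sketch (all Gaussians zero-mean; x̃ past, x present):
    Ĩ(β) = E_{p(x̃,x)}[log q(x|x̃)^β] − E_{p(x)}[log E_{p(x̃)} q(x|x̃)^β].
    Both terms are Gaussian integrals.  With S(β) = Σ⁻¹ + β Ãᵀ Σ_q⁻¹ Ã and
    C = Σ − Σ_lagᵀÃᵀ − ÃΣ_lag + ÃΣÃᵀ the closed form is

        Ĩ(β) = ½ log det(S Σ) + β/2 [tr(Σ_q⁻¹ Σ) − tr(Σ_q⁻¹ C)]
               − β²/2 tr(S⁻¹ Ãᵀ Σ_q⁻¹ Σ Σ_q⁻¹ Ã),

    verified against a Monte-Carlo evaluation of the defining expectations
    in the test suite.
    """

    def __init__(self, model: StationaryGaussianModel, partition: Partition):
        n = model.n
        sigma = model.sigma_x
        sigma_lag = model.sigma_lag
        a_tilde = np.zeros((n, n))
        sigma_q = np.zeros((n, n))
        for p in partition.parts:
            idx = np.asarray(p, dtype=int)
            block = sigma[np.ix_(idx, idx)]
            lag_block = sigma_lag[np.ix_(idx, idx)]
            cf = cho_factor(block, lower=True, check_finite=False)
            # regression of part-present on part-past
            a_tilde[np.ix_(idx, idx)] = cho_solve(cf, lag_block,
                                                  check_finite=False).T
            cond = block - lag_block.T @ cho_solve(cf, lag_block,
                                                   check_finite=False)
            sigma_q[np.ix_(idx, idx)] = 0.5 * (cond + cond.T)
        try:
            cf_q = cho_factor(sigma_q, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise DegenerateModelError(
                "restricted decoder conditional covariance Σ_q is singular"
            ) from exc
        sigma_q_inv = cho_solve(cf_q, np.eye(n), check_finite=False)
        self.model = model
        self.a_tilde = a_tilde
        self.sigma_q = sigma_q
        try:
            self.sigma_inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError as exc:
            raise DegenerateModelError("Σ(X) is singular") from exc
        # K = Ãᵀ Σ_q⁻¹ Ã;  W = Ãᵀ Σ_q⁻¹ Σ Σ_q⁻¹ Ã
        t = sigma_q_inv @ a_tilde
        self.K = a_tilde.T @ t
        self.W = t.T @ sigma @ t
        mismatch = (sigma - sigma_lag.T @ a_tilde.T - a_tilde @ sigma_lag
                    + a_tilde @ sigma @ a_tilde.T)
        self.mismatch_cov = 0.5 * (mismatch + mismatch.T)
        self.tr_q_sigma = float(np.trace(sigma_q_inv @ sigma))
        self.tr_q_mismatch = float(np.trace(sigma_q_inv @ self.mismatch_cov))
        self.logdet_sigma = logdet_pd(sigma, "sigma_x")

    def value(self, beta: float) -> float:
        if beta < 0:
            raise UsageError(f"beta must be ≥ 0, got {beta}")
        s = self.sigma_inv + beta * self.K
        try:
            cf = cho_factor(s, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise DegenerateModelError(
                f"posterior precision S(β) singular at beta={beta}"
            ) from exc
        logdet_s = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        quad = float(np.trace(cho_solve(cf, self.W, check_finite=False)))
        return (0.5 * (logdet_s + self.logdet_sigma)
                + 0.5 * beta * (self.tr_q_sigma - self.tr_q_mismatch)
                - 0.5 * beta * beta * quad)

    def state(self, beta: float) -> MismatchedDecodingState:
        return MismatchedDecodingState(
            beta=float(beta),
            i_tilde=self.value(beta),
            a_tilde=self.a_tilde,
            sigma_q=self.sigma_q,
            precision_sum=self.sigma_inv + beta * self.K,
            mismatch_cov=self.mismatch_cov,
        )


def i_tilde_beta(model: StationaryGaussianModel, partition: Partition,
                 beta: float) -> MismatchedDecodingState:
    """Evaluate the mismatched-decoding curve Ĩ(β) for one partition,
    exposing the decoder's intermediate matrices.  Ĩ(0) = 0 and
    Ĩ(β) ≤ TDMI."""
    return _MismatchedDecoder(model, partition).state(beta)


#: Initial β search bracket; the matched decoder sits at β = 1, so [0, 2]
#: brackets typical optima.  Doubled (up to _BETA_MAX) if the argmax lands
#: within 1e-6 of the upper end.
_BETA_HI = 2.0
_BETA_MAX = 2.0 ** 16
_BETA_XATOL = 1e-9


def _maximise_i_tilde(decoder: _MismatchedDecoder):
    hi = _BETA_HI
    while True:
        res = minimize_scalar(lambda b: -decoder.value(b), bounds=(0.0, hi),
                              method="bounded",
                              options={"xatol": _BETA_XATOL})
        if not res.success:
            raise SolverError(
                f"β maximisation did not converge on [0, {hi}]",
                diagnostics={"scipy_result": res},
            )
        if hi - res.x > 1e-6 or hi >= _BETA_MAX:
            return float(res.x), float(-res.fun), int(res.nfev)
        hi *= 2.0


def effective_info_phi_star(model: StationaryGaussianModel,
                            partition: Partition) -> float:
    """Φ*(P) = TDMI − max_β Ĩ(β) ∈ [0, TDMI]."""
    decoder = _MismatchedDecoder(model, partition)
    _, i_star, _ = _maximise_i_tilde(decoder)
    return tdmi(model) - i_star


def phi_star(model: StationaryGaussianModel, scheme: str = "even") -> MeasureResult:
    """Decoder-based integrated information Φ*: the partition-scanned
    mismatched-decoding loss, with β* reported in diagnostics."""
    mip = find_mip(model, effective_info_phi_star, scheme=scheme)
    decoder = _MismatchedDecoder(model, mip.partition)
    beta_star, i_star, nfev = _maximise_i_tilde(decoder)
    return MeasureResult(
        "phi_star", mip.value, mip.partition,
        {"beta_star": beta_star, "i_star": i_star, "beta_evals": nfev,
         "candidates_evaluated": mip.candidates_evaluated},
    )


# ---------------------------------------------------------------------------
# Geometric Φ_G (M-projection)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometricProjectionState:
    """Solution of the M-projection onto the severed-links manifold.

    ``a_prime`` is the restricted lag-τ coupling (zero across parts),
    ``sigma_e`` the full model's residual covariance Σ(X_t|X_{t−τ}),
    ``sigma_e_prime`` the restricted model's residual implied by the
    projection's stationarity condition.  ``constraint_residual`` is the
    largest within-part entry of Σ(X)(A−A′)Σ(E)′⁻¹, which vanishes at the
    exact projection.
    """

    a_prime: np.ndarray
    sigma_e: np.ndarray
    sigma_e_prime: np.ndarray
    objective: float
    constraint_residual: float
    iterations: int
    converged: bool


_PHI_G_MAX_ITER = 500
_PHI_G_RESID_TOL = 1e-6


def phi_g(model: StationaryGaussianModel, partition: Partition,
          max_iter: int = _PHI_G_MAX_ITER) -> GeometricProjectionState:
    """M-projection distance for one partition.

    The restricted model keeps the within-part blocks of the lag-τ coupling
    free and fixes the cross-part blocks to zero (severing causal links while
    leaving noise correlations intact).  The restricted residual covariance
    is eliminated analytically, Σ(E)′ = Σ(E) + (A−A′)Σ(X)(A−A′)ᵀ, leaving a
    smooth unconstrained convex minimisation of
    ½ log det Σ(E)′ − ½ log det Σ(E) over the within-part entries of A′,
    solved by iterated linearisation of the first-order condition with an
    L-BFGS fallback (analytic gradient −(Σ(E)′⁻¹ (A−A′) Σ(X)) restricted to
    the free entries).  The
    projection's first-order condition — within-part blocks of
    Σ(X)(A−A′)Σ(E)′⁻¹ vanishing — is evaluated at the solution as a
    convergence diagnostic.
    """
    n = model.n
    sigma = model.sigma_x
    a_eff = model.effective_coupling()
    sigma_e = model.sigma_present_given_past()
    try:
        logdet_e = logdet_pd(sigma_e, "sigma_e")
    except DegenerateModelError as exc:
        raise DegenerateModelError(
            f"residual covariance Σ(E) is degenerate: {exc}"
        ) from exc

    mask = np.zeros((n, n), dtype=bool)
    for p in partition.parts:
        idx = np.asarray(p, dtype=int)
        mask[np.ix_(idx, idx)] = True
    iw = np.flatnonzero(mask.ravel())

    def unpack(x):
        a_prime = np.zeros((n, n))  # cross-part blocks stay severed at 0
        a_prime.ravel()[iw] = x
        return a_prime

    # Primary solver: iterated linearisation of the first-order condition.
    # With Σ(E)′ frozen, the stationarity condition is linear in the free
    # entries of A′: (Σ(E)′⁻¹ A′ Σ(X))|_within = (Σ(E)′⁻¹ A Σ(X))|_within.
    # Solve, refresh Σ(E)′ from the eliminated constraint, repeat.  The
    # objective is convex, and the iteration converges linearly; L-BFGS with
    # the analytic gradient polishes (or replaces) the solution if it stalls.
    a_prime = np.where(mask, a_eff, 0.0)
    iterations = 0
    fp_converged = False
    try:
        for iterations in range(1, max_iter + 1):
            delta = a_eff - a_prime
            sp = sigma_e + delta @ sigma @ delta.T
            spi = np.linalg.inv(0.5 * (sp + sp.T))
            lhs = np.kron(spi, sigma.T)[np.ix_(iw, iw)]
            rhs = (spi @ a_eff @ sigma).ravel()[iw]
            new = unpack(np.linalg.solve(lhs, rhs))
            step = np.abs(new - a_prime).max()
            a_prime = new
            if step < 1e-9 * max(1.0, np.abs(a_prime).max()):
                fp_converged = True
                break
    except np.linalg.LinAlgError:
        fp_converged = False

    if not fp_converged:
        def objective(x):
            delta = a_eff - unpack(x)
            sp = sigma_e + delta @ sigma @ delta.T
            sp = 0.5 * (sp + sp.T)
            try:
                cf = cho_factor(sp, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros_like(x)
            f = float(np.sum(np.log(np.diag(cf[0])))) - 0.5 * logdet_e
            grad_full = -cho_solve(cf, delta @ sigma, check_finite=False)
            return f, grad_full.ravel()[iw]

        res = minimize(objective, a_prime.ravel()[iw], jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-16,
                                "gtol": 1e-10})
        a_prime = unpack(res.x)
        iterations += int(res.nit)
    delta = a_eff - a_prime
    sigma_e_prime = sigma_e + delta @ sigma @ delta.T
    sigma_e_prime = 0.5 * (sigma_e_prime + sigma_e_prime.T)
    # first-order (stationarity) condition of the projection: within-part
    # blocks of Σ(E)′⁻¹ (A−A′) Σ(X) vanish — the transpose-convention form
    # of the blockwise constraint Σ(X)(A−A′)ᵀΣ(E)′⁻¹|_ii = 0
    resid_mat = np.linalg.solve(sigma_e_prime, delta @ sigma)
    resid = float(np.abs(np.where(mask, resid_mat, 0.0)).max())
    value = 0.5 * (logdet_pd(sigma_e_prime, "sigma_e_prime") - logdet_e)
    state = GeometricProjectionState(
        a_prime=a_prime,
        sigma_e=sigma_e,
        sigma_e_prime=sigma_e_prime,
        objective=value,
        constraint_residual=resid,
        iterations=iterations,
        converged=bool(resid < _PHI_G_RESID_TOL),
    )
    if not state.converged:
        raise SolverError(
            f"Φ_G projection did not converge at partition {partition} "
            f"(residual {resid:.3e}, {iterations} iterations)",
            diagnostics={"state": state},
        )
    return state


def _effective_info_phi_g(model, partition):
    return phi_g(model, partition).objective


def phi_g_measure(model: StationaryGaussianModel,
                  scheme: str = "even") -> MeasureResult:
    """Geometric integrated information Φ_G at the MIP, with the projection
    constraint residual in diagnostics."""
    mip = find_mip(model, _effective_info_phi_g, scheme=scheme)
    state = phi_g(model, mip.partition)
    return MeasureResult(
        "phi_g", mip.value, mip.partition,
        {"constraint_residual": state.constraint_residual,
         "iterations": state.iterations,
         "candidates_evaluated": mip.candidates_evaluated},
    )


# ---------------------------------------------------------------------------
# Transfer entropy and causal density
# ---------------------------------------------------------------------------

def transfer_entropy(model: StationaryGaussianModel, source, target,
                     conditioning=()) -> float:
    """Conditional transfer entropy TE(source → target | conditioning) at the
    model's lag: I(source_{t−τ}; target_t | conditioning_{t−τ}, target_{t−τ}).
    """
    n = model.n
    src = [int(i) for i in source]
    tgt = [int(i) for i in target]
    cond = [int(i) for i in conditioning]
    if set(src) & set(tgt) or set(src) & set(cond) or set(tgt) & set(cond):
        raise UsageError("source, target and conditioning parts must be disjoint")
    joint = model.joint
    # past indices are 0..n−1, present indices n..2n−1
    return conditional_mi(
        joint,
        target_idx=[n + j for j in tgt],
        source_idx=src,
        conditioning_idx=cond + tgt,
    )


def causal_density(model: StationaryGaussianModel, partition: Partition) -> float:
    """CD(P) = (1/(r(r−1))) Σ_{i≠j} TE(M^i → M^j | M^[ij]).

    For bipartitions the conditioning set M^[ij] is empty.  Non-negative and
    bounded above by TDMI.
    """
    parts = partition.parts
    r = len(parts)
    if r < 2:
        raise UsageError("causal density requires at least two parts")
    total = 0.0
    for i in range(r):
        for j in range(r):
            if i == j:
                continue
            rest = [v for k, p in enumerate(parts) if k not in (i, j) for v in p]
            total += transfer_entropy(model, parts[i], parts[j], rest)
    return total / (r * (r - 1))


def cd_measure(model: StationaryGaussianModel, scheme: str = "even") -> MeasureResult:
    """Causal density minimised over the partition scheme (the atomic scheme
    reproduces the measure's original variable-wise definition)."""
    mip = find_mip(model, causal_density, scheme=scheme)
    return MeasureResult("cd", mip.value, mip.partition,
                         {"candidates_evaluated": mip.candidates_evaluated})


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

MEASURE_NAMES = ("tdmi", "sigma_bar", "phi", "phi_tilde", "psi",
                 "phi_star", "phi_g", "cd")

_SCANNED = {
    "phi": phi_wms,
    "phi_tilde": phi_tilde,
    "psi": psi,
    "phi_star": phi_star,
    "phi_g": phi_g_measure,
    "cd": cd_measure,
}


def compute_all(model: StationaryGaussianModel, measures=None,
                scheme: str = "even") -> dict:
    """Compute a selection of measures (default: all eight quantities).

    Returns a dict mapping measure name to :class:`MeasureResult`.
    """
    names = MEASURE_NAMES if measures is None else tuple(measures)
    out = {}
    for name in names:
        if name == "tdmi":
            out[name] = MeasureResult("tdmi", tdmi(model))
        elif name == "sigma_bar":
            out[name] = MeasureResult("sigma_bar", avg_abs_correlation(model))
        elif name in _SCANNED:
            out[name] = _SCANNED[name](model, scheme=scheme)
        else:
            raise UsageError(
                f"unknown measure {name!r}; expected one of {MEASURE_NAMES}"
            )
    return out
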