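# Methods

## Scope and model class

`iintegrate` computes dynamical (empirical-distribution) integrated
information measures for stationary Gaussian first-order vector
autoregressive processes

    X_{t+1} = A X_t + ε_t,      ε_t ~ N(0, Σ(ε)),  white in time.

The process is stable, hence stationary, iff the spectral radius ρ(A) < 1.
Its stationary covariance Σ(X) solves the discrete-time Lyapunov equation
Σ = AΣAᵀ + Σ(ε) (solved with `scipy.linalg.solve_discrete_lyapunov`; the
residual ‖Σ − AΣAᵀ − Σ(ε)‖∞ is verified to 1e-10 relative to scale), and the
lag-τ covariance is Σ(X_{t−τ}, X_t) = Σ(X)(Aᵀ)^τ.  Everything downstream
consumes only the pair (Σ(X), Σ_lag) plus the lag — the
`StationaryGaussianModel` — so measures are equally well-defined for models
that do not come from an explicit coupling matrix (e.g. time-reversed
models, whose lagged covariance is the transpose).  All information
quantities are differential and reported in nats (the CLI can convert to
bits); conditioning is the Schur complement Σ(X|Y) = Σ(X) −
Σ(X,Y)Σ(Y)⁻¹Σ(Y,X), and Gaussian entropy/MI reduce to log-determinants
computed by Cholesky factorisation.

Only the linear-Gaussian branches of the measures are implemented.
Discrete-state variants, nearest-neighbour estimators for non-Gaussian
continuous data, and perturbational (maximum-entropy) measures are out of
scope.

## Partitions and the minimum information partition

A partition splits the n variables into r disjoint non-empty parts.  Each
measure is defined per partition as an *effective information* and scanned
for its minimum.  The package default — used by every experiment runner —
is the **unnormalised objective over even bipartitions** (both parts of
size n/2, C(n, n/2)/2 candidates, exhaustively enumerated in canonical
order).  This keeps the partition-search method fixed while measures are
compared, and avoids the normalisation coefficient K(P) =
(r−1)·min_k H(M^k), which compensates for unbalanced parts but is known to
be numerically unstable — for differential entropies K can even be
negative.  The normalised search and the all-bipartitions and atomic
schemes remain available per call; a warning is emitted when a normalised
search encounters K ≤ 0.  Ties break lexicographically on the canonical
form, making MIP results fully deterministic.

CD and Φ_G were originally defined on the atomic partition; they are
scanned over even bipartitions by default here, for comparability, and the
atomic scheme reproduces the original definitions.

## The measures

With M^k the parts of partition P, x̃ the past state X_{t−τ} and x the
present X_t:

* **TDMI** I(X_{t−τ}; X_t) — total predictive information; control.
* **Σ̄** — mean |correlation| over off-diagonal pairs; control.
* **Φ (whole-minus-sum)** φ = TDMI − Σ_k I(M^k_{t−τ}; M^k_t).  Can be
  negative (net redundancy).
* **Φ̃ (stochastic interaction)** φ̃ = Σ_k H(M^k_{t−τ}|M^k_t) −
  H(X_{t−τ}|X_t) ≥ 0.  The identity φ̃ = φ + Σ_k H(M^k_t) − H(X_t) (the
  instantaneous multi-information) is enforced as a cross-check at 1e-9.
* **ψ (integrated synergy)** TDMI − I_∪, where under the
  minimum-mutual-information PID the union information collapses to
  I_∪ = max_k I(M^k_{t−τ}; X_t) for Gaussians.  The partition scan makes
  the maximisation over partitions intrinsic to the measure; both the
  per-partition functional and the scanned measure are exposed, since the
  original definition folds the partition optimum into the formula itself.
* **Φ\* (decoder-based)** TDMI − I*, with I* = max_{β≥0} Ĩ(β) the
  mismatched-decoding information of the partition-factorised decoder
  q(x|x̃) = ∏_k p(m^k|m̃^k).
* **Φ_G (geometric)** the KL divergence from p(x̃, x) to its M-projection
  onto models whose cross-part *causal* links are severed (instantaneous
  noise correlations remain free).
* **CD (causal density)** mean pairwise conditional transfer entropy
  TE(M^i→M^j|M^[ij]) = I(M^i_{t−τ}; M^j_t | M^j_{t−τ}, M^[ij]_{t−τ});
  the conditioning set is empty for bipartitions.

### The Gaussian mismatched-decoding curve

Ĩ(β) = E_p[log q(x|x̃)^β] − E_{p(x)}[ log E_{p(x̃)} q(x|x̃)^β ].  The
decoder q is Gaussian with block-diagonal regression Ã (per-part
regressions m̃^k ↦ m^k) and block-diagonal conditional covariance Σ_q.
Carrying out the two Gaussian integrals gives, with
S(β) = Σ⁻¹ + β ÃᵀΣ_q⁻¹Ã and C = Σ − Σ_lagᵀÃᵀ − ÃΣ_lag + ÃΣÃᵀ,

    Ĩ(β) = ½ log det(S(β)Σ) + (β/2)[tr(Σ_q⁻¹Σ) − tr(Σ_q⁻¹C)]
           − (β²/2) tr(S(β)⁻¹ ÃᵀΣ_q⁻¹ Σ Σ_q⁻¹Ã).

Sanity anchors: Ĩ(0) = 0; when the partition exactly decouples the
dynamics, Ĩ(1) = TDMI (matched decoding); Ĩ(β) ≤ TDMI always.  The formula
is derived in-package and validated against a Monte-Carlo evaluation of the
defining expectations (3-standard-error agreement at β ∈ {0.5, 1, 1.5}) in
the test suite.  Ĩ is concave in β, so I* is found by bounded scalar
maximisation on [0, 2] (β-tolerance 1e-9), doubling the bracket whenever
the argmax lands within 1e-6 of the upper end; β = 1 is the matched
decoder, so [0, 2] brackets typical optima.

### The M-projection

For Gaussians the projection problem reduces to minimising
½ log det Σ(E)′ − ½ log det Σ(E) over restricted couplings A′, where
Σ(E) = Σ(X_t|X_{t−τ}) and Σ(E)′ = Σ(E) + (A−A′)Σ(X)(A−A′)ᵀ eliminates the
restricted residual analytically.  Severing cross-part causal links means
the cross-part blocks of A′ are fixed at zero and only within-part entries
are free; the noise of the restricted model remains fully coupled.  The
first-order (stationarity) condition — within-part blocks of
Σ(E)′⁻¹(A−A′)Σ(X) vanish — is linear in A′ once Σ(E)′ is frozen, so the
primary solver iterates: solve that linear system, refresh Σ(E)′, repeat
until the update falls below 1e-9 (relative).  The objective is convex; if
the iteration stalls, L-BFGS with the analytic gradient finishes the job.
The stationarity residual is re-evaluated at the returned solution and must
be below 1e-6, else a solver error carrying the best iterate is raised.
The effective coupling is recovered from the model itself
(A_eff = Σ_lagᵀΣ(X)⁻¹, equal to A for an AR(1) at τ = 1, and to A^τ at
larger lags), which keeps Φ_G defined for time-reversed models.

## Degeneracy policy

As the noise correlation c → 1 (or for otherwise rank-deficient models)
some determinants in the formulae vanish and measures genuinely diverge.
The package surfaces this: any covariance whose smallest eigenvalue falls
below 1e-10 of its largest raises a typed degeneracy error naming the
offending block, rather than regularising or returning ±∞.  Sweep runners
catch these errors and record the grid point with status ``degenerate``
(similarly ``unstable`` for ρ(A) ≥ 1 and ``solver-failure``), so result
tables always account for every requested point.

## Simulation oracle and synthetic systems

Nothing in the package estimates from samples; the trajectory simulator
exists purely as an independent oracle.  It draws the initial state from
the stationary distribution and discards 1,000 burn-in steps
(belt-and-braces given the stationary start), so recorded trajectories are
stationary from the first row.  Agreement between analytic and simulated
(lagged) covariances is asserted at 3 standard errors with batch-means
standard errors (100 batches of 10⁴ steps), which accounts for the
autocorrelation of the AR process.

The property-test battery uses random stable systems: coupling matrices
with standard-normal entries rescaled to a spectral radius uniform on
[0.3, 0.9], and noise covariances formed as random correlation matrices
shrunk halfway towards the identity — correlated enough to exercise the
measures, far enough from degeneracy that all six remain computable.  The
battery has 120 systems (60 each at n = 2 and n = 4), fixed seed.

These synthetic systems emulate the *statistical* setting — stable linear
Gaussian dynamics with correlated noise — not any particular empirical
system.  Passing tests therefore demonstrate correctness of the formulae
and optimisers under the model class, and the qualitative phenomenology of
the measures on that class; they say nothing about robustness to
non-Gaussianity, nonstationarity, or estimation noise in real time series,
which are explicitly out of scope.

## Experiment presets and problem sizes

* Two-node sweeps: c ∈ {0, 0.05, …, 0.95}, a ∈ {0.025, …, 0.475} (a = 0.5
  is the exact stability threshold of the symmetric two-node coupling:
  eigenvalues {0, 2a}).
* Network suite: fully connected (A), bidirectional ring (D), small-world
  ring (E), unidirectional ring (F), each normalised to spectral radius
  0.9 with uncorrelated unit noise.  E adds two directed long-range edges
  (defaults 1→5 and 4→8, 1-based); their placement is a free modelling
  choice and is exposed as a parameter.  The externally optimised networks
  (binary and weighted) are not bundled — their weight matrices are not
  constructible from a rule — and are supported through the headerless-CSV
  loader.
* Erdős–Rényi experiments: directed 0/1 adjacencies at edge density ρ,
  normalised to spectral radius 0.9, equicorrelated noise c.  Desk presets:
  a 5×5 (ρ, c) grid at 10 samples per cell, and a 2,000-network scatter
  with (ρ, c) drawn uniformly (c ≤ 0.9, keeping the equicorrelated noise
  comfortably positive definite at n = 8).  These sizes were chosen so the
  complete suite runs on a single desktop core in minutes while the
  qualitative features (interior-density and interior-correlation peaks of
  ψ, Φ*, Φ_G, CD) are already stable.

## Numerical behaviour worth knowing

* φ̃ as a function of noise correlation in the two-node system at a = 0.4
  is *not* strictly monotone: exact computation shows a shallow interior
  minimum near c ≈ 0.1 (φ̃ = 0.2113 at c = 0, 0.2059 at c = 0.1) before the
  steep growth and divergence towards c → 1.  The dip (~1.7 %) is confirmed
  by an independent joint-entropy evaluation and by simulation plug-in
  estimates, and is invisible at typical figure resolution.
* Φ_G of the two-node model is exactly independent of noise correlation;
  the sweep reproduces this to < 1e-9 even though the value comes from a
  numerical projection.
* Under the unnormalised even-bipartition convention, φ̃ is *exactly*
  invariant to diagonal rescaling of the variables: the log|det D| terms of
  the whole and of the parts cancel per partition.  The measure's
  traditional non-invariance enters only through the normalised partition
  selection (K(B) is not rescaling invariant and can flip the argmin), which
  this package exposes as an option.
* Φ_G under the pairwise severed-links formulation implemented here is
  *not* time-symmetric in general: the constraint conditions the future on
  the past, and the projection of the time-reversed model can land at a
  different distance (differences up to ~0.05 nats on random 4-node
  systems, confirmed against an independent derivative-free multi-start
  optimiser).  Φ and Φ̃ are time-symmetric to machine precision.
* Monotonicity checks in the experiment suite use non-strict comparisons
  with 1e-9 slack on adjacent grid points, since several trends are exact
  invariances subject only to round-off.

## Known limitations

* Exhaustive partition enumeration only; the even-bipartition default is
  O(C(n, n/2)) per measure and the package targets n ≲ 12.  Heuristic MIP
  search (spectral, modularity or submodular methods) is not implemented.
* Φ_G and Φ* are solver-based; their values are reproducible to optimiser
  tolerance (~1e-9), not bit-exactly.
* AR order 1 only; longer memory must be embedded by state augmentation
  before using the package.
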