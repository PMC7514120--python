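# iintegrate

Integrated information and dynamical complexity measures for stationary
Gaussian vector autoregressive systems.

## What this is for

How much more information does a system generate as a whole than its parts
do separately?  Measures of *integrated information* ("Φ" measures) make
this question quantitative and sit at the heart of Integrated Information
Theory in consciousness science, but they are equally of interest wherever
the balance of integration and segregation in a multivariate dynamical
system matters — network neuroscience, complex systems, and directed
information-flow analysis in systems biology.

Several inequivalent operationalisations exist.  This package implements
six of them, side by side, with a common partition-search convention, for
the one model class where everything has a closed form (or a small smooth
optimisation): stable AR(1) processes

    X_{t+1} = A X_t + ε_t,   ε_t ~ N(0, Σ(ε)),   ρ(A) < 1,

whose stationary covariance solves the discrete Lyapunov equation
Σ = AΣAᵀ + Σ(ε) and whose lag-τ covariance is Σ(Aᵀ)^τ.  For a partition
P = {M¹, …, Mʳ} of the variables (even bipartitions by default), with past
state X_{t−τ} and present X_t:

| measure | definition (per partition, minimised over partitions) |
|---|---|
| TDMI | I(X_{t−τ}; X_t) — total predictive information (control) |
| Σ̄ | mean off-diagonal |correlation| (control) |
| Φ | TDMI − Σ_k I(M^k_{t−τ}; M^k_t) — whole minus sum; may be negative |
| Φ̃ | Σ_k H(M^k_{t−τ}\|M^k_t) − H(X_{t−τ}\|X_t) — stochastic interaction |
| ψ | TDMI − max_k I(M^k_{t−τ}; X_t) — synergy under the MMI decomposition |
| Φ\* | TDMI − max_β Ĩ(β) — loss under a partition-factorised decoder |
| Φ_G | min KL from p to models with cross-part causal links severed |
| CD | mean pairwise conditional transfer entropy between parts |

All values are in nats.  See `docs/methods.md` for the Gaussian formulas,
the mismatched-decoding derivation, the M-projection solver, and the
degeneracy policy near singular noise (c → 1).

## Worked example

The minimal non-trivial system: two nodes, every coupling entry a = 0.4,
unit-variance noise with correlation c = 0.5.

```sh
$ iintegrate compute --model model.json
measure     value_nats  partition
tdmi        0.510826    -
sigma_bar   0.785714    -
phi         -0.202941   1|2
phi_tilde   0.277372    1|2
psi         0.087177    1|2
phi_star    0.034562    1|2
phi_g       0.205698    1|2
cd          0.066766    1|2
```

with `model.json` containing
`{"A": [[0.4, 0.4], [0.4, 0.4]], "noise_corr_c": 0.5}`.

Reading the numbers: the system carries 0.51 nats of predictive
information across one time step (TDMI).  Whole-minus-sum Φ is *negative*
— the strongly correlated noise makes the parts' predictions redundant, so
the sum of part informations exceeds the whole.  Φ̃ stays positive (it adds
back the instantaneous multi-information), while the three measures that
track conjoined integration and segregation — ψ, Φ\* and CD — are small and
shrink to 0 as c → 1, when the two nodes become copies of each other.
Φ_G is unaffected by noise correlation entirely: severing the causal links
still permits correlated noise, so only the coupling matters.

The same quantities are available programmatically:

```python
from iintegrate import two_node, build_model, compute_all

model = build_model(two_node(a=0.4, c=0.5))
results = compute_all(model)          # dict of MeasureResult
print(results["phi_star"].value, results["phi_star"].diagnostics["beta_star"])
```

Experiment sweeps (two-node grids, the eight-node topology ranking,
Erdős–Rényi grids and scatters) are run via
`iintegrate sweep <experiment> --config sweep.yaml --out results.csv
[--plots dir/]` or the functions in `iintegrate.experiments`, and produce
tidy CSV with one row per (grid point, sample, measure), each carrying a
status (`ok` / `degenerate` / `unstable` / `solver-failure`).

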