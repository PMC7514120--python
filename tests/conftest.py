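"""Shared fixtures: seeded batteries of random stable AR systems and their
precomputed measure values (plain, variable-rescaled, time-reversed), reused
across the property suites so each system is only solved once."""

import numpy as np
import pytest

from iintegrate import (ARSystem, build_model, cd_measure, phi_g_measure,
                        phi_star, phi_tilde, phi_wms, psi,
                        random_stable_system, tdmi)

BATTERY_SEED = 20260
N_PER_SIZE = {2: 60, 4: 60}  # ≥ 100 systems total

SCANNED = {
    "phi": phi_wms,
    "phi_tilde": phi_tilde,
    "psi": psi,
    "phi_star": phi_star,
    "phi_g": phi_g_measure,
    "cd": cd_measure,
}


def _measure_values(model):
    out = {name: fn(model).value for name, fn in SCANNED.items()}
    out["tdmi"] = tdmi(model)
    return out


def rescale_system(sys: ARSystem, d: np.ndarray) -> ARSystem:
    """Congruence rescaling X → DX: A → DAD⁻¹, Σ(ε) → DΣ(ε)D."""
    D = np.diag(d)
    Dinv = np.diag(1.0 / d)
    return ARSystem(D @ sys.A @ Dinv, D @ sys.sigma_eps @ D)


@pytest.fixture(scope="session")
def battery():
    """Seeded random stable systems, n ∈ {2, 4}, with their lag-1 models."""
    rng = np.random.default_rng(BATTERY_SEED)
    systems = []
    for n, count in N_PER_SIZE.items():
        for _ in range(count):
            sys = random_stable_system(n, rng)
            systems.append((sys, build_model(sys)))
    return systems


@pytest.fixture(scope="session")
def battery_results(battery):
    """All partition-scanned measures on each battery system, plus the same
    measures after a random positive diagonal rescaling and on the
    time-reversed model."""
    rng = np.random.default_rng(BATTERY_SEED + 1)
    results = []
    for sys, model in battery:
        d = rng.uniform(0.5, 2.0, size=sys.n)
        rescaled_model = build_model(rescale_system(sys, d))
        reversed_model = model.time_reversed()
        results.append({
            "system": sys,
            "model": model,
            "plain": _measure_values(model),
            "rescaled": _measure_values(rescaled_model),
            "reversed": _measure_values(reversed_model),
        })
    return results
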