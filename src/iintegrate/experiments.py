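"""Simulation experiment runners.

Each runner evaluates the full measure set (or a subset) on a family of
AR(1) systems and returns a tidy :class:`pandas.DataFrame` with one row per
(grid point, sample, measure).  Every row carries the full parameter set,
the seed, the minimising partition (serialised 1-based, ``"1,2|3,4"``) and a
status: ``ok``, ``degenerate`` (a required covariance was singular),
``unstable`` (spectral radius ≥ 1) or ``solver-failure``.  Grid points whose
systems cannot be built still appear, with the appropriate status, so row
accounting is exact: #rows = #grid-points × #samples × #measures.

Experiments
-----------
* :func:`run_two_node_c_sweep` — the two-node system at fixed coupling,
  sweeping the noise correlation c.
* :func:`run_two_node_ac_grid` — the same system over a (coupling a, noise
  correlation c) grid.
* :func:`run_network_ranking` — the eight-node topology suite at fixed
  spectral radius with uncorrelated noise, plus per-measure rank orderings.
* :func:`run_er_grid` — means over seeded Erdős–Rényi samples on a (edge
  density ρ, noise correlation c) grid.
* :func:`run_sigma_scatter` — Erdős–Rényi networks at random (ρ, c),
  scattered against their average absolute correlation Σ̄.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ar_model import ARSystem, build_model
from .errors import (DegenerateModelError, SolverError, StationarityError,
                     UsageError)
from .measures import MEASURE_NAMES, compute_all
from .networks import (NetworkSpec, ar_system_from_network, erdos_renyi,
                       suite_network, two_node)

__all__ = [
    "SweepConfig",
    "run_two_node_c_sweep",
    "run_two_node_ac_grid",
    "run_network_ranking",
    "run_er_grid",
    "run_sigma_scatter",
    "aggregate_grid",
]

#: Default sweep grids (desk scale).
DEFAULT_C_GRID = tuple(np.round(np.arange(0.0, 1.0, 0.05), 10))
DEFAULT_A_GRID = tuple(np.round(np.arange(0.025, 0.5, 0.025), 10))
DEFAULT_ER_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.2), 10))


@dataclass
class SweepConfig:
    """Configuration for the CLI sweep runner (YAML-loadable)."""

    experiment: str
    a: float = 0.4
    a_grid: Sequence[float] = DEFAULT_A_GRID
    c: float = 0.0
    c_grid: Sequence[float] = DEFAULT_C_GRID
    rho_grid: Sequence[float] = DEFAULT_ER_GRID
    er_c_grid: Sequence[float] = DEFAULT_ER_GRID
    n_samples: int = 50
    n_draws: int = 2000
    n: int = 8
    radius: float = 0.9
    seed: int = 0
    tau: int = 1
    measures: Optional[Sequence[str]] = None
    scheme: str = "even"
    network_files: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise UsageError(f"unknown sweep config keys: {sorted(unknown)}")
        return cls(**raw)


def _measure_rows(sys: ARSystem, params: dict, measures, scheme, tau=1):
    """Evaluate the requested measures on one system, one row per measure,
    converting model failures into per-row statuses."""
    names = tuple(measures) if measures is not None else MEASURE_NAMES
    rows = []
    try:
        model = build_model(sys, tau=tau)
    except StationarityError:
        model = None
        base_status = "unstable"
    except DegenerateModelError:
        model = None
        base_status = "degenerate"
    for name in names:
        row = dict(params)
        row["measure"] = name
        if model is None:
            row.update(value=np.nan, partition="", status=base_status)
        else:
            try:
                res = compute_all(model, measures=[name], scheme=scheme)[name]
                row.update(
                    value=res.value,
                    partition=res.partition.to_string() if res.partition else "",
                    status="ok",
                )
                if "beta_star" in res.diagnostics:
                    row["beta_star"] = res.diagnostics["beta_star"]
                if "constraint_residual" in res.diagnostics:
                    row["constraint_residual"] = res.diagnostics["constraint_residual"]
            except (DegenerateModelError,):
                row.update(value=np.nan, partition="", status="degenerate")
            except StationarityError:
                row.update(value=np.nan, partition="", status="unstable")
            except SolverError:
                row.update(value=np.nan, partition="", status="solver-failure")
        rows.append(row)
    return rows


def run_two_node_c_sweep(a: float = 0.4, c_grid=DEFAULT_C_GRID, tau: int = 1,
                         measures=None, scheme: str = "even") -> pd.DataFrame:
    """Sweep the two-node system over noise correlation at fixed coupling."""
    rows = []
    for c in c_grid:
        params = {"a": float(a), "c": float(c), "tau": tau}
        try:
            sys = two_node(a, c)
        except DegenerateModelError:
            names = tuple(measures) if measures is not None else MEASURE_NAMES
            rows += [dict(params, measure=m, value=np.nan, partition="",
                          status="degenerate") for m in names]
            continue
        rows += _measure_rows(sys, params, measures, scheme, tau)
    return pd.DataFrame(rows)


def run_two_node_ac_grid(a_grid=DEFAULT_A_GRID, c_grid=DEFAULT_C_GRID,
                         tau: int = 1, measures=None,
                         scheme: str = "even") -> pd.DataFrame:
    """Sweep the two-node system over a (coupling, noise correlation) grid.

    Grid points with a ≥ 0.5 are unstable (spectral radius 2a ≥ 1) and are
    recorded with status ``unstable``.
    """
    rows = []
    for a in a_grid:
        for c in c_grid:
            params = {"a": float(a), "c": float(c), "tau": tau}
            try:
                sys = two_node(a, c)
            except DegenerateModelError:
                names = tuple(measures) if measures is not None else MEASURE_NAMES
                rows += [dict(params, measure=m, value=np.nan, partition="",
                              status="degenerate") for m in names]
                continue
            rows += _measure_rows(sys, params, measures, scheme, tau)
    return pd.DataFrame(rows)


def run_network_ranking(networks=None, network_files=None, radius: float = 0.9,
                        c: float = 0.0, tau: int = 1, measures=None,
                        scheme: str = "even"):
    """Evaluate all measures on a suite of named networks at a fixed
    spectral radius, and rank the networks per measure (highest first).

    ``networks`` may be a sequence of :class:`NetworkSpec`; by default the
    constructively specified suite (A, D, E, F) is used, and any externally
    optimised matrices in ``network_files`` (name → CSV path) are appended.
    Returns ``(table, ranking)`` where ``ranking`` maps each measure to the
    network names ordered by decreasing value.
    """
    from .networks import SUITE_NAMES, load_network

    if networks is None:
        networks = [suite_network(name) for name in SUITE_NAMES]
        for name, path in (network_files or {}).items():
            networks = list(networks) + [load_network(path, name=name)]
    rows = []
    for spec in networks:
        params = {"network": spec.name, "radius": radius, "c": float(c),
                  "tau": tau}
        try:
            sys = ar_system_from_network(spec, radius=radius, c=c)
        except (UsageError, DegenerateModelError):
            names = tuple(measures) if measures is not None else MEASURE_NAMES
            rows += [dict(params, measure=m, value=np.nan, partition="",
                          status="degenerate") for m in names]
            continue
        rows += _measure_rows(sys, params, measures, scheme, tau)
    table = pd.DataFrame(rows)
    ok = table[table.status == "ok"]
    ranking = {
        measure: list(grp.sort_values("value", ascending=False)["network"])
        for measure, grp in ok.groupby("measure")
    }
    return table, ranking


def run_er_grid(rho_grid=DEFAULT_ER_GRID, c_grid=DEFAULT_ER_GRID,
                n_samples: int = 50, seed: int = 0, n: int = 8,
                radius: float = 0.9, tau: int = 1, measures=None,
                scheme: str = "even") -> pd.DataFrame:
    """Erdős–Rényi grid experiment: ``n_samples`` networks per (ρ, c) cell.

    Per-sample failures (e.g. an all-zero adjacency at low ρ) are recorded
    with their status; cell means should be taken over ``status == "ok"``
    rows (see :func:`aggregate_grid`).  Deterministic given ``seed``.
    """
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(len(rho_grid) * len(c_grid) * n_samples))
    rows = []
    for rho in rho_grid:
        for c in c_grid:
            for k in range(n_samples):
                params = {"rho": float(rho), "c": float(c), "sample": k,
                          "seed": seed, "tau": tau}
                spec = erdos_renyi(n, rho, np.random.default_rng(next(children)))
                try:
                    sys = ar_system_from_network(spec, radius=radius, c=c)
                except (UsageError, DegenerateModelError):
                    names = (tuple(measures) if measures is not None
                             else MEASURE_NAMES)
                    rows += [dict(params, measure=m, value=np.nan, partition="",
                                  status="degenerate") for m in names]
                    continue
                rows += _measure_rows(sys, params, measures, scheme, tau)
    return pd.DataFrame(rows)


def aggregate_grid(table: pd.DataFrame, by=("rho", "c")) -> pd.DataFrame:
    """Per-cell mean/variance of each measure over successful samples."""
    ok = table[table.status == "ok"]
    agg = (ok.groupby([*by, "measure"])["value"]
           .agg(["mean", "var", "count"]).reset_index())
    return agg


def run_sigma_scatter(n_draws: int = 2000, seed: int = 0, n: int = 8,
                      radius: float = 0.9, tau: int = 1, measures=None,
                      scheme: str = "even", c_max: float = 0.9) -> pd.DataFrame:
    """Erdős–Rényi networks at random (ρ, c), each row tagged with the
    network's average absolute correlation Σ̄ for scatter analysis.

    ρ is drawn uniformly from [0, 1) and c uniformly from [0, c_max].
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    names = tuple(measures) if measures is not None else MEASURE_NAMES
    if "sigma_bar" not in names:
        names = names + ("sigma_bar",)
    for k in range(n_draws):
        rho = float(rng.random())
        c = float(rng.uniform(0.0, c_max))
        params = {"rho": rho, "c": c, "sample": k, "seed": seed, "tau": tau}
        spec = erdos_renyi(n, rho, rng)
        try:
            sys = ar_system_from_network(spec, radius=radius, c=c)
        except (UsageError, DegenerateModelError):
            rows += [dict(params, measure=m, value=np.nan, partition="",
                          status="degenerate") for m in names]
            continue
        rows += _measure_rows(sys, params, names, scheme, tau)
    table = pd.DataFrame(rows)
    # annotate every row with its network's Σ̄ for direct scatter plotting
    sb = (table[table.measure == "sigma_bar"]
          .set_index("sample")["value"].rename("sigma_bar_value"))
    return table.join(sb, on="sample")
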