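"""Network constructors for the simulation experiments.

Covers the two-node system with symmetric coupling and correlated noise,
the eight-node topology suite (fully connected, bidirectional ring,
small-world ring, unidirectional ring, plus a CSV loader for externally
supplied weighted matrices), equicorrelated noise covariances, and seeded
directed Erdős–Rényi samples.  All constructed or sampled adjacencies have
zero diagonal (no self-loops); weights are 0/1 before global scaling, which
is applied downstream either as a multiplicative coupling factor or by
normalising the spectral radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .ar_model import ARSystem, normalize_spectral_radius
from .errors import DegenerateModelError, UsageError
from .gaussian_info import check_covariance

__all__ = [
    "NetworkSpec",
    "two_node",
    "equicorrelated_noise",
    "suite_network",
    "load_network",
    "erdos_renyi",
    "ar_system_from_network",
    "random_stable_system",
    "SUITE_NAMES",
]

#: Constructively specified members of the eight-node suite.  B and C (the
#: genetic-algorithm-optimised binary and weighted networks) must be supplied
#: as CSV files via :func:`load_network`.
SUITE_NAMES = ("A", "D", "E", "F")


@dataclass(frozen=True)
class NetworkSpec:
    """A named adjacency matrix with provenance (constructed / sampled /
    loaded from file)."""

    name: str
    adjacency: np.ndarray
    provenance: dict

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=float)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise UsageError(f"adjacency must be square, got shape {adj.shape}")
        object.__setattr__(self, "adjacency", adj)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name,
                       "adjacency": self.adjacency.tolist(),
                       "provenance": self.provenance}, fh, indent=2)


def two_node(a: float, c: float) -> ARSystem:
    """The minimal two-node system: coupling matrix with all four entries a,
    unit-variance noise with correlation c.

    Spectral radius is 2a (eigenvalues {0, 2a}), so stationarity requires
    a < 0.5.  Construction itself only validates |c| < 1; stability is
    checked where stationary statistics are needed.
    """
    if not abs(c) < 1:
        raise DegenerateModelError(
            f"noise correlation c must satisfy |c| < 1 for a PD covariance, got {c}"
        )
    A = np.full((2, 2), float(a))
    sigma_eps = np.array([[1.0, c], [c, 1.0]])
    return ARSystem(A=A, sigma_eps=sigma_eps)


def equicorrelated_noise(n: int, c: float) -> np.ndarray:
    """Unit-diagonal covariance with constant off-diagonal c, modelling a
    shared noise source.  Positive definite iff c ∈ (−1/(n−1), 1)
    (eigenvalues are 1 + (n−1)c and 1 − c)."""
    if n < 1:
        raise UsageError(f"n must be ≥ 1, got {n}")
    lo = -1.0 / (n - 1) if n > 1 else -1.0
    if not (lo < c < 1.0):
        raise DegenerateModelError(
            f"equicorrelated noise with n={n} is positive definite only for "
            f"c in ({lo:.6g}, 1), got {c}"
        )
    sigma = np.full((n, n), float(c))
    np.fill_diagonal(sigma, 1.0)
    return check_covariance(sigma, "equicorrelated noise")


def _ring(n: int, bidirectional: bool) -> np.ndarray:
    adj = np.zeros((n, n))
    for i in range(n):
        adj[i, (i + 1) % n] = 1.0
        if bidirectional:
            adj[(i + 1) % n, i] = 1.0
    return adj


#: Default long-range edges added to the bidirectional ring to form the
#: small-world network E (1-based: 1→5 and 4→8).  Configurable because the
#: exact placement is a modelling choice.
DEFAULT_LONG_RANGE_EDGES = ((0, 4), (3, 7))


def suite_network(name: str, n: int = 8,
                  long_range_edges=DEFAULT_LONG_RANGE_EDGES) -> NetworkSpec:
    """Constructively specified eight-node topologies.

    * ``A`` — fully connected, no self-loops (56 directed edges at n=8);
    * ``D`` — bidirectional ring (16 edges);
    * ``E`` — bidirectional ring plus directed long-range shortcuts
      (default two, giving a small-world-like topology);
    * ``F`` — unidirectional ring (8 edges).

    The optimised networks ``B`` and ``C`` are not constructible from a rule
    and must be loaded from CSV via :func:`load_network`.
    """
    name = name.upper()
    if name == "A":
        adj = np.ones((n, n)) - np.eye(n)
    elif name == "D":
        adj = _ring(n, bidirectional=True)
    elif name == "E":
        adj = _ring(n, bidirectional=True)
        for (i, j) in long_range_edges:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise UsageError(f"invalid long-range edge ({i}, {j}) for n={n}")
            adj[i, j] = 1.0
    elif name == "F":
        adj = _ring(n, bidirectional=False)
    elif name in ("B", "C"):
        raise UsageError(
            f"network {name} is an externally optimised matrix; "
            "supply it as a CSV file via load_network()"
        )
    else:
        raise UsageError(f"unknown suite network {name!r}; expected one of A, D, E, F")
    return NetworkSpec(name=name, adjacency=adj, provenance={"kind": "constructed"})


def load_network(path, name: str | None = None) -> NetworkSpec:
    """Load an adjacency matrix from a headerless CSV of comma-separated
    reals (one row per node)."""
    try:
        adj = np.loadtxt(path, delimiter=",", ndmin=2)
    except Exception as exc:
        raise UsageError(f"could not parse adjacency CSV {path}: {exc}") from exc
    if adj.shape[0] != adj.shape[1]:
        raise UsageError(
            f"adjacency CSV {path} is not square: shape {adj.shape}"
        )
    return NetworkSpec(name=name or str(path), adjacency=adj,
                       provenance={"kind": "file", "path": str(path)})


def erdos_renyi(n: int, rho: float, seed) -> NetworkSpec:
    """Directed Erdős–Rényi sample: each off-diagonal entry is 1 with
    probability rho, independently; self-loops removed.  Reproducible given
    ``seed`` (int or Generator)."""
    if not (0.0 <= rho < 1.0):
        raise UsageError(f"edge density rho must be in [0, 1), got {rho}")
    if n < 2:
        raise UsageError(f"n must be ≥ 2, got {n}")
    rng = np.random.default_rng(seed)
    adj = (rng.random((n, n)) < rho).astype(float)
    np.fill_diagonal(adj, 0.0)
    return NetworkSpec(
        name=f"ER(n={n}, rho={rho})", adjacency=adj,
        provenance={"kind": "sampled", "rho": rho},
    )


def ar_system_from_network(spec: NetworkSpec, radius: float = 0.9,
                           c: float = 0.0) -> ARSystem:
    """Animate a network with AR(1) dynamics: normalise the adjacency to the
    given spectral radius and attach equicorrelated noise.

    An all-zero adjacency cannot be normalised and raises
    :class:`UsageError`; resampling policy is the caller's.
    """
    A = normalize_spectral_radius(spec.adjacency, radius)
    return ARSystem(A=A, sigma_eps=equicorrelated_noise(spec.n, c))


def random_stable_system(n: int, rng, radius_range=(0.3, 0.9),
                         noise_corr_scale: float = 0.5) -> ARSystem:
    """A random stable AR(1) system for property-test batteries.

    The coupling matrix has standard-normal entries rescaled to a spectral
    radius drawn uniformly from ``radius_range``; the noise covariance is a
    random correlation-like PD matrix, W Wᵀ scaled to unit diagonal and
    shrunk towards the identity by ``noise_corr_scale`` to stay comfortably
    away from degeneracy.
    """
    rng = np.random.default_rng(rng)
    while True:
        A = rng.standard_normal((n, n))
        if np.abs(np.linalg.eigvals(A)).max() > 1e-8:
            break
    A = normalize_spectral_radius(A, rng.uniform(*radius_range))
    w = rng.standard_normal((n, n))
    cov = w @ w.T + 1e-3 * np.eye(n)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    sigma_eps = noise_corr_scale * corr + (1.0 - noise_corr_scale) * np.eye(n)
    return ARSystem(A=A, sigma_eps=sigma_eps)
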