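"""Partitions of a system's variables and the minimum-information-partition
search.

A partition splits the n variables into r disjoint, non-empty parts.
Integrated information is the effective information across the partition
where it is smallest — the minimum information partition (MIP).  Following
the convention used throughout the simulation studies here, the default
search space is the set of *even bipartitions* (both parts of size n/2) and
the objective is the *unnormalised* effective information; searching over
all bipartitions, or over the atomic partition alone, and normalising by
K(P) = (r−1)·min_k H(M^k) are available as options.  Normalisation is known
to introduce instabilities and is off by default.

Partitions are kept in canonical form (each part sorted ascending, parts
ordered by their smallest element) so enumeration order, and therefore MIP
tie-breaking, is deterministic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

from .ar_model import StationaryGaussianModel
from .errors import UsageError
from .gaussian_info import gaussian_entropy

__all__ = [
    "Partition",
    "MIPResult",
    "enumerate_even_bipartitions",
    "enumerate_bipartitions",
    "atomic_partition",
    "normalisation_K",
    "find_mip",
]


@dataclass(frozen=True)
class Partition:
    """An ordered list of disjoint, non-empty index sets covering 0..n−1."""

    parts: tuple

    def __init__(self, parts):
        canon = tuple(sorted((tuple(sorted(p)) for p in parts), key=lambda p: p[0] if p else -1))
        object.__setattr__(self, "parts", canon)
        flat = [i for p in canon for i in p]
        if any(len(p) == 0 for p in canon):
            raise UsageError("partition parts must be non-empty")
        if len(set(flat)) != len(flat):
            raise UsageError(f"partition parts overlap: {canon}")
        if sorted(flat) != list(range(len(flat))):
            raise UsageError(
                f"partition must cover exactly the indices 0..{len(flat) - 1}: {canon}"
            )

    @property
    def n(self) -> int:
        return sum(len(p) for p in self.parts)

    @property
    def r(self) -> int:
        return len(self.parts)

    @property
    def is_bipartition(self) -> bool:
        return self.r == 2

    def to_string(self) -> str:
        """Serialise as e.g. ``"1,2|3,4"`` with 1-based variable indices."""
        return "|".join(",".join(str(i + 1) for i in p) for p in self.parts)

    @classmethod
    def from_string(cls, s: str) -> "Partition":
        """Parse the 1-based ``"1,2|3,4"`` serialisation."""
        try:
            parts = [[int(tok) - 1 for tok in chunk.split(",")] for chunk in s.split("|")]
        except ValueError as exc:
            raise UsageError(f"malformed partition string {s!r}") from exc
        return cls(parts)

    def __str__(self) -> str:
        return self.to_string()


def atomic_partition(n: int) -> Partition:
    """The n-singleton partition {1}|{2}|…|{n}."""
    if n < 1:
        raise UsageError(f"n must be ≥ 1, got {n}")
    return Partition([(i,) for i in range(n)])


def enumerate_bipartitions(n: int) -> list:
    """All 2^(n−1) − 1 unordered bipartitions, canonical, deterministic order.

    Deduplication fixes variable 0 in the first part.
    """
    if n < 2:
        raise UsageError(f"bipartitions require n ≥ 2, got {n}")
    out = []
    rest = list(range(1, n))
    for k in range(0, n - 1):
        for combo in itertools.combinations(rest, k):
            first = (0,) + combo
            second = tuple(i for i in rest if i not in combo)
            out.append(Partition([first, second]))
    return out


def enumerate_even_bipartitions(n: int) -> list:
    """All C(n, n/2)/2 unordered bipartitions with equal-sized parts."""
    if n < 2 or n % 2 != 0:
        raise UsageError(
            f"even bipartitions are only defined for even n ≥ 2, got {n}"
        )
    half = n // 2
    out = []
    rest = list(range(1, n))
    for combo in itertools.combinations(rest, half - 1):
        first = (0,) + combo
        second = tuple(i for i in rest if i not in combo)
        out.append(Partition([first, second]))
    return out


def _candidates(n: int, scheme: str) -> list:
    if scheme in ("even", "even-bipartitions"):
        return enumerate_even_bipartitions(n)
    if scheme in ("all", "all-bipartitions"):
        return enumerate_bipartitions(n)
    if scheme == "atomic":
        return [atomic_partition(n)]
    raise UsageError(
        f"unknown partition scheme {scheme!r}; "
        "expected 'even', 'all' or 'atomic'"
    )


def normalisation_K(partition: Partition, model: StationaryGaussianModel) -> float:
    """Balancing coefficient K(P) = (r−1) · min_k H(M^k) over stationary
    marginals.

    For differential entropies K can be negative (low-variance parts); this
    is reported as-is, never clamped.
    """
    entropies = [
        gaussian_entropy(model.marginalize(p).sigma_x, name=f"part {p}")
        for p in partition.parts
    ]
    return (partition.r - 1) * min(entropies)


@dataclass(frozen=True)
class MIPResult:
    """Outcome of a MIP search: the minimising partition, the unnormalised
    effective information there, and search diagnostics."""

    partition: Partition
    value: float
    normalised_value: Optional[float]
    candidates_evaluated: int


def find_mip(
    model: StationaryGaussianModel,
    effective_info: Callable[[StationaryGaussianModel, Partition], float],
    scheme: str = "even",
    normalised: bool = False,
) -> MIPResult:
    """Exhaustively minimise an effective-information function over a
    partition scheme.

    With ``normalised=True`` the argmin is taken over value / K(P) while the
    reported ``value`` remains the unnormalised effective information at the
    chosen partition.  Ties break towards the earlier partition in canonical
    enumeration order.  Failures of the objective at a candidate are re-raised
    with the candidate identified.
    """
    candidates = _candidates(model.n, scheme)
    best = None
    for part in candidates:
        try:
            value = float(effective_info(model, part))
        except Exception as exc:
            raise type(exc)(
                f"effective information failed at partition {part}: {exc}"
            ) from exc
        if normalised:
            k = normalisation_K(part, model)
            if k <= 0:
                warnings.warn(
                    f"normalisation K(P) = {k:.4g} ≤ 0 at partition {part}; "
                    "normalised ordering is unreliable here",
                    RuntimeWarning,
                    stacklevel=2,
                )
            key = value / k
        else:
            k = None
            key = value
        if best is None or key < best[0]:
            best = (key, value, part, k)
    key, value, part, k = best
    return MIPResult(
        partition=part,
        value=value,
        normalised_value=(key if normalised else None),
        candidates_evaluated=len(candidates),
    )
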