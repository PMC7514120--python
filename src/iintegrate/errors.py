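"""Exception hierarchy.

All errors raised by the library derive from :class:`IntegrateError` so that
sweep runners can catch everything model-related in one clause while letting
programming errors propagate.
"""


class IntegrateError(Exception):
    """Base class for all library errors."""


class UsageError(IntegrateError, ValueError):
    """Invalid arguments: malformed partitions, bad index sets, odd n for
    even-bipartition schemes, non-conformable matrices."""


class DegenerateModelError(IntegrateError):
    """A covariance (sub)matrix required to be positive definite is singular
    or indefinite; typically the noise-correlation c → 1 limit."""


class StationarityError(IntegrateError):
    """The AR coupling matrix has spectral radius ≥ 1, so no stationary
    distribution exists."""


class SolverError(IntegrateError):
    """A numerical optimiser failed to converge. Carries the best iterate
    found so far in ``diagnostics``."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
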