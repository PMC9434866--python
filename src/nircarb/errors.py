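"""Exception hierarchy.

Every error raised by nircarb derives from :class:`NircarbError`, so callers
can catch the package's failures with a single ``except`` clause while still
getting ``ValueError`` semantics from standard-library code paths.
"""


class NircarbError(Exception):
    """Base class for all nircarb errors."""


class InvalidGridError(NircarbError, ValueError):
    """Wavelength grid is empty, non-monotone, or has a non-positive step."""


class GridMismatchError(NircarbError, ValueError):
    """Two objects that must share a wavelength grid do not."""


class InvalidDesignError(NircarbError, ValueError):
    """A tissue design violates its invariants (negative sd, n < 1, ...)."""


class MissingReplicateError(NircarbError, ValueError):
    """A sample has no replicate spectra."""


class ZeroVarianceError(NircarbError, ValueError):
    """An operation that divides by a standard deviation met a constant."""


class AssayInconsistencyError(NircarbError, ValueError):
    """Digestion total below the free-sugar sum: starch would be negative."""


class DomainError(NircarbError, ValueError):
    """Numeric input outside the operation's domain (e.g. R <= 0)."""


class DegenerateResponseError(NircarbError, ValueError):
    """Response vector has zero variance; no calibration is possible."""


class DegenerateDirectionError(NircarbError, ValueError):
    """Regression vector is zero; projection direction undefined."""


class InsufficientSamplesError(NircarbError, ValueError):
    """Too few samples for the requested degrees of freedom."""


class GroupingError(NircarbError, ValueError):
    """Group labels do not form the required two-level comparison."""


class SplitSizeError(NircarbError, ValueError):
    """Too few samples to populate both calibration and validation sets."""


class ParseError(NircarbError, ValueError):
    """Malformed input file; the message names the offending location."""


class ConfigError(NircarbError, ValueError):
    """Scenario configuration failed validation."""
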