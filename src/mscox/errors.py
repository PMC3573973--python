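"""Exception taxonomy for the mscox pipeline.

Exit-code mapping for the CLI lives in :mod:`mscox.cli`; library code only
raises these types.
"""


class MscoxError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(MscoxError, ValueError):
    """A physiological measurement is non-finite or out of its valid range."""


class ConfigurationError(MscoxError, ValueError):
    """An option is outside its supported set (threshold, CI level, ...)."""


class MissingBaselineError(MscoxError, ValueError):
    """A subject's visit series has no baseline (visit 0) record."""


class MalformedInputError(MscoxError, ValueError):
    """Structural problem in input tables (duplicates, gaps, bad types)."""


class SchemaError(MscoxError, ValueError):
    """A CSV does not conform to the documented column schema."""


class FitError(MscoxError, RuntimeError):
    """A model fit failed to converge; ``role`` names the offending model."""

    def __init__(self, message: str, role: str | None = None):
        super().__init__(message)
        self.role = role


class PositivityError(MscoxError, RuntimeError):
    """A denominator probability hit 0 or 1 on a contributing row."""


class InsufficientEventsError(MscoxError, ValueError):
    """Fewer than two outcome events: hazard ratio not estimable."""


class InsufficientVariationError(MscoxError, ValueError):
    """A design column (typically exposure) is constant."""


class InsufficientOracleError(MscoxError, ValueError):
    """Counterfactual oracle requested with too small a simulation size."""


class BootstrapError(MscoxError, RuntimeError):
    """Too many bootstrap replicates failed to converge."""
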