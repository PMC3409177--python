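"""Exception hierarchy shared across the package."""

from __future__ import annotations


class SynaptenacityError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SynaptenacityError, ValueError):
    """An invalid parameter value; ``field`` names the offending parameter."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SchemaError(SynaptenacityError, ValueError):
    """A tabular input violates the expected schema.

    ``rows`` holds 0-based data-row indices of offending rows when the
    problem is row-local (empty for file-level problems such as missing
    columns).
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (rows: {self.rows[:20]})"
        super().__init__(message)


class InsufficientDataError(SynaptenacityError, ValueError):
    """Not enough data points / puncta / curves for the requested operation."""


class CorrectionError(SynaptenacityError, ValueError):
    """Photobleaching correction is impossible (zero or negative baselines)."""


class FitError(SynaptenacityError, RuntimeError):
    """Model fitting failed in a way that cannot be reported as a flagged fit."""
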