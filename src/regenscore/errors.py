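"""Exception hierarchy.

Validation errors signal bad user input (exit code 2 in the CLI);
insufficient-data errors signal inputs that are well formed but too small
for the requested computation (exit code 3).
"""


class RegenScoreError(Exception):
    """Base class for all package errors."""


class ValidationError(RegenScoreError):
    """Input fails a type invariant or schema check."""


class RubricError(RegenScoreError):
    """Unknown rubric item or system."""


class MeasurementError(ValidationError):
    """Physically impossible measurement (e.g. ash mass exceeding dry mass)."""


class NoGapError(RegenScoreError):
    """All scores identical: no gap exists to threshold on."""


class InsufficientDataError(RegenScoreError):
    """Too few rows / levels / groups for the requested model."""


class InsufficientDepthError(ValidationError):
    """Soil profile does not reach the requested reference mass."""


class ConfigError(RegenScoreError):
    """Invalid simulation or model-spec configuration."""
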