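"""Exception hierarchy shared across the package."""


class AvmodError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AvmodError):
    """Input data violates a schema or referential-integrity rule.

    Where possible the message names the offending file, column and
    1-based data row so the problem can be located in the CSV directly.
    """


class InvalidStimulusError(AvmodError):
    """A stimulus specification violates its invariants (e.g. duration <= 0)."""


class OutOfEpochError(AvmodError):
    """A requested analysis window falls outside a trial's recorded epoch."""


class NotApplicableError(AvmodError):
    """An operation was requested for a trial type it is not defined for."""


class DegenerateDesignError(AvmodError):
    """A statistical design cannot be estimated (empty cell, zero variance,
    collinear columns, too few observations)."""


class ConfigError(AvmodError):
    """A run or simulation configuration is inconsistent."""
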