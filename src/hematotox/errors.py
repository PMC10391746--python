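"""Exception hierarchy shared across the package."""


class HematotoxError(Exception):
    """Base class for all package errors."""


class SchemaError(HematotoxError):
    """A CSV file does not match the documented schema (e.g. missing column)."""


class CohortValidationError(HematotoxError):
    """Patient-level data violate an invariant (bad value, duplicate id, ...)."""


class ScoringError(HematotoxError):
    """Baseline labs cannot be scored under the requested missingness policy."""


class ConfigError(HematotoxError):
    """A generator or pipeline configuration value is invalid."""


class StatisticalError(HematotoxError):
    """A statistical routine cannot produce a valid answer
    (empty group, one-class outcome, separation, non-convergence)."""
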