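"""Exception types shared across the package."""


class SemdriveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SemdriveError, ValueError):
    """A design, parameter set, or configuration value is invalid."""


class DomainError(SemdriveError, ValueError):
    """An object (genotype, feature, place) is outside its declared domain."""


class ParameterError(SemdriveError, ValueError):
    """Parameters admit no valid solution (e.g. a population below replacement)."""


class ConfigValidationError(ConfigurationError):
    """A scenario configuration failed validation.

    Carries the full list of violations (key path + message), not just the
    first one encountered.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__(
            "invalid scenario configuration:\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


class AlignmentError(SemdriveError, ValueError):
    """Ensemble members do not share a common time grid."""
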