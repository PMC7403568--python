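"""Exception hierarchy for cohortcomp."""


class CohortCompError(Exception):
    """Base class for all cohortcomp errors."""


class ConfigurationError(CohortCompError):
    """A scenario or assumption configuration is invalid; names the offending field."""


class ValidationError(CohortCompError):
    """An input array or table violates a domain invariant."""


class RateMagnitudeError(ValidationError):
    """Combined occurrence-exposure rates are too large for the mid-period
    person-years approximation (d + e >= 2 over a one-year interval)."""


class BracketingError(CohortCompError):
    """A root-finding target lies outside the achievable bracket."""


class ConvergenceError(CohortCompError):
    """An iterative procedure failed to converge within its iteration budget."""


class CalibrationError(CohortCompError):
    """Migration calibration cannot reach the target population."""


class ClassificationError(CohortCompError):
    """A birthplace unit is missing from a classification mapping."""
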