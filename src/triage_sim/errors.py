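"""Exception hierarchy for the triage simulation pipeline."""


class TriageSimError(Exception):
    """Base class for all package errors."""


class ParameterError(TriageSimError, ValueError):
    """Invalid generator or model parameters."""


class DomainError(TriageSimError, ValueError):
    """Input outside the mathematical domain of a score formula."""


class CalibrationError(TriageSimError, RuntimeError):
    """Requested calibration target is unattainable."""


class ExportFormatError(TriageSimError, ValueError):
    """Raw-export file does not conform to the CSV dialect."""


class ConfigurationError(TriageSimError, ValueError):
    """Inconsistent scenario / simulation configuration."""


class StateError(TriageSimError, ValueError):
    """ICU state violates a structural precondition (e.g. not full)."""


class PolicyUsageError(TriageSimError, TypeError):
    """A ranking operation was invoked for a policy that has no ranking key."""
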