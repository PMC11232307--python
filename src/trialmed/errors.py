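"""Exception types shared across the package."""


class TrialMedError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TrialMedError):
    """A generator or run configuration is invalid."""


class SequencingError(TrialMedError):
    """A pipeline stage was called before its prerequisites (e.g. mediators
    before randomisation)."""


class InsufficientDataError(TrialMedError):
    """Too few usable rows for a model fit."""


class DegenerateDataError(TrialMedError):
    """A response or scale is degenerate (constant outcome, zero sd)."""


class DataValidationError(TrialMedError):
    """A dataset violates the participant-record schema."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class CalibrationError(TrialMedError):
    """A calibration target is unreachable within the coefficient bounds."""


class ConvergenceError(TrialMedError):
    """Sampler diagnostics failed the convergence gate."""


class AlignmentError(TrialMedError):
    """Model fits that must share rows or transforms do not."""
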