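"""Exception hierarchy.

Every failure mode a caller is expected to handle gets its own class so
pipelines can log-and-continue on per-clip problems while configuration
mistakes fail fast.
"""


class KinescoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KinescoreError):
    """Invalid configuration value (unknown dialect, bad model config, ...)."""


class EmptyInputError(KinescoreError):
    """An input file or collection contained nothing usable."""


class DegenerateInputError(KinescoreError):
    """Input too short/degenerate for the requested operation."""


class NoActivityError(KinescoreError):
    """No frame exceeded the onset thresholds; no task window found."""


class InsufficientDataError(KinescoreError):
    """Too few samples for calibration or fitting."""


class MissingJointError(KinescoreError):
    """A joint required by the task is entirely missing in the window."""


class InsufficientCyclesError(KinescoreError):
    """Fewer movement cycles than the operation requires."""


class InsufficientRatersError(KinescoreError):
    """A rater panel with fewer than two scores."""


class TrainingDivergenceError(KinescoreError):
    """Training produced a non-finite loss."""
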