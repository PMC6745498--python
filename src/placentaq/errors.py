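"""Exception hierarchy with CLI exit codes.

Exit-code contract: 0 ok, 2 configuration error, 3 data error,
4 pipeline error. Landmark-detection failures are data errors so that
cohort analysis can record them per curve instead of aborting.
"""


class PlacentaqError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PlacentaqError):
    """Invalid configuration or parameters (exit code 2)."""

    exit_code = 2


class DataError(PlacentaqError):
    """Malformed or degenerate input data (exit code 3)."""

    exit_code = 3


class PipelineError(PlacentaqError):
    """A whole pipeline stage failed (exit code 4)."""

    exit_code = 4


class LandmarkError(DataError):
    """A signal-intensity curve has no valid landmark structure."""


class NoFirstMaximum(LandmarkError):
    """No interior local maximum exceeding the initial signal intensity."""


class NoRecoveryLimb(LandmarkError):
    """The interior minimum sits at the final timepoint: nothing recovers."""
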