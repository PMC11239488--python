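"""Exception hierarchy.

Two broad families matter for the CLI exit-code contract: configuration
problems (bad parameters, unknown schedules, malformed configs -> exit 2)
and data problems (degenerate fits, corrupt files, layout violations ->
exit 3).
"""


class OptophysError(Exception):
    """Base class for all package errors."""


class ConfigError(OptophysError):
    """Invalid parameters, unknown schedule/schema names, bad config files."""


class DataError(OptophysError):
    """Problems with the data itself (degenerate, corrupt, inconsistent)."""


class LayoutError(DataError):
    """Requested events do not fit inside the session or overlap windows."""


class DegenerateFitError(DataError):
    """A regression cannot be fit (e.g. zero-variance regressor)."""


class NormalizationError(DataError):
    """The fitted baseline used as the dF/F denominator is non-positive."""


class DegenerateBaselineError(DataError):
    """A trial's baseline has zero standard deviation; z-scoring undefined."""

    def __init__(self, trial_id, message=None):
        self.trial_id = trial_id
        super().__init__(message or f"zero baseline s.d. for trial {trial_id}")


class OverlapError(ConfigError):
    """Pulse or response windows overlap (duty-cycle violation)."""
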