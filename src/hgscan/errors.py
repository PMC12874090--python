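"""Exception hierarchy. Input errors map to CLI exit code 2, internal errors to 3."""


class HgscanError(Exception):
    """Base class for all package errors."""


class InputError(HgscanError, ValueError):
    """Malformed or inconsistent user input (bad sequence, missing sample, ...)."""


class ProfileBuildError(HgscanError, ValueError):
    """Profile construction failed (e.g. all-gap alignment, no match columns)."""


class CalibrationError(HgscanError, ValueError):
    """E-value calibration failed (e.g. degenerate null score distribution)."""


class PipelineError(HgscanError, RuntimeError):
    """Internal invariant violation during pipeline orchestration."""
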