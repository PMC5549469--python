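"""Exception hierarchy.

Hard contract violations raise; per-frame stage failures inside the
pipeline are *returned* as failure records (see :mod:`fbcine.lvcenter`),
never raised, so one bad frame cannot abort a whole slice.
"""


class FbcineError(Exception):
    """Base class for all package errors."""


class ParameterError(FbcineError, ValueError):
    """A configuration value violates its invariant."""


class RangeError(FbcineError, IndexError):
    """An index (frame number, window start) is out of range."""


class DegenerateInputError(FbcineError, ValueError):
    """Input is degenerate for the operation (constant image, collinear points)."""


class EllipseFitError(FbcineError, ValueError):
    """Conic fit failed or did not yield an ellipse."""


class SignalError(FbcineError, ValueError):
    """A 1-D signal is too short or otherwise unusable."""


class TraceError(FbcineError, ValueError):
    """Too many per-frame failures to build a motion trace."""

    def __init__(self, msg: str, failed_frames=()):
        super().__init__(msg)
        self.failed_frames = tuple(failed_frames)


class PeriodEstimationError(FbcineError, ValueError):
    """No significant periodicity found in the cardiac signal."""


class DetectionError(FbcineError, RuntimeError):
    """ED/ES identification failed (e.g. every frame pair invalid)."""


class FormatError(FbcineError, ValueError):
    """A file could not be read as a cine stack."""


class ConfigError(FbcineError, ValueError):
    """Run configuration is invalid."""
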