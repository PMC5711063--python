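"""Exception hierarchy for the compensation pipeline.

Every stage raises a narrow subclass of :class:`RespcompError` so that the
experiment runner can abort a single arm and keep going.
"""


class RespcompError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(RespcompError, ValueError):
    """A numeric parameter violates its precondition (e.g. period <= 0)."""


class KindMismatchError(RespcompError, TypeError):
    """A displacement trace was required but a voltage trace was given (or vice versa)."""


class TraceFormatError(RespcompError, ValueError):
    """A trace file violates the two-column uniform-sampling contract."""


class GeometryError(RespcompError, ValueError):
    """A projection distance lies outside the source-to-imaging-plane segment."""


class DegenerateFitError(RespcompError, ValueError):
    """The surrogate has no variance; gain/shift cannot be identified."""


class AlignmentError(RespcompError, ValueError):
    """Two traces or grids that must share sampling/geometry do not."""


class DegenerateTraceError(RespcompError, ValueError):
    """No breathing cycle can be detected in the trace."""


class GridError(RespcompError, ValueError):
    """The dose grid cannot hold the requested field or motion extent."""


class CalibrationError(RespcompError, ValueError):
    """Penumbra calibration target cannot be bracketed or met."""


class CoverageError(RespcompError, ValueError):
    """The motion trace does not cover the requested irradiation window."""


class ConfigError(RespcompError, ValueError):
    """An experiment configuration file is invalid."""
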