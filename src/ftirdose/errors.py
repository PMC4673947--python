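"""Exception hierarchy for the ftirdose package.

Every error raised by the library derives from :class:`FtirDoseError`, so
callers (and the CLI) can catch one base class at stage boundaries.
"""


class FtirDoseError(Exception):
    """Base class for all ftirdose errors."""


class FormatError(FtirDoseError):
    """A delimited-text file does not match the expected dialect."""


class GridError(FtirDoseError):
    """A wavenumber axis is non-monotone, non-uniform, or out of range."""


class WindowError(FtirDoseError):
    """A requested wavenumber window does not overlap the grid."""


class ExtrapolationError(FtirDoseError):
    """Resampling was requested outside the source grid."""


class DataError(FtirDoseError):
    """Spectrum values are non-finite or otherwise unusable."""


class NormalizationError(FtirDoseError):
    """A constant spectrum cannot be min-max normalized."""


class ControlReferenceError(FtirDoseError):
    """No control-dose spectra (or colony counts) available as reference."""


class DesignError(FtirDoseError):
    """The experimental design cannot support the requested split or CV."""


class ParameterError(FtirDoseError):
    """A parameter is outside its admissible range."""


class DegeneracyError(FtirDoseError):
    """The data are degenerate for the requested fit (e.g. constant y)."""


class ShapeError(FtirDoseError):
    """Matrix/vector dimensions do not agree."""


class ConditioningError(FtirDoseError):
    """A linear system inside the PLS fit is too ill-conditioned to trust."""
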