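"""Exception hierarchy for the ramanclass package."""


class RamanClassError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(RamanClassError):
    """A parameter or configuration value violates its contract."""


class DataFormatError(RamanClassError):
    """A delimited-text spectra file is malformed (ragged rows, bad cells,
    non-monotone wavenumber axis)."""


class EmptyRegionError(RamanClassError):
    """A wavenumber region selects no axis points."""


class InsufficientDataError(RamanClassError):
    """An operation needs more spectra (or both class labels) than provided."""


class DegenerateInputError(RamanClassError):
    """Numerically degenerate input: zero variance, zero-norm row, etc."""


class ShapeError(RamanClassError):
    """Array dimensions are incompatible."""


class UndefinedAUCError(RamanClassError):
    """ROC-AUC requested with only one class present."""


class DivergenceError(RamanClassError):
    """Training produced a non-finite loss."""
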