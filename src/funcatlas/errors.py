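"""Exception hierarchy shared across the package."""


class FuncatlasError(Exception):
    """Base class for all package errors."""


class GeometryError(FuncatlasError):
    """Invalid mesh/grid definition or out-of-range element index."""


class EmptyROIError(FuncatlasError):
    """An ROI was requested that no subject possesses."""


class InsufficientDataError(FuncatlasError):
    """Too few subjects, folds, runs or records for the requested analysis."""


class UndefinedCorrelationError(FuncatlasError):
    """Correlation requested on a variable with zero variance."""


class MissingDataError(FuncatlasError):
    """An element lacks response amplitudes (e.g. outside brain coverage)."""


class ConfigurationError(FuncatlasError):
    """Inconsistent spaces, unknown mode, or missing input files."""
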