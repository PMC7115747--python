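"""Exception hierarchy.

Every error raised by this package derives from :class:`RamanChemoError`,
so callers can catch one type at a pipeline boundary.
"""


class RamanChemoError(Exception):
    """Base class for all ramanchemo errors."""


class FormatError(RamanChemoError):
    """A spectrum or table file could not be parsed (carries a line number)."""


class InputError(RamanChemoError):
    """Arguments violate an operation's preconditions."""


class ParameterError(RamanChemoError):
    """A configuration or tuning parameter is out of its valid range."""


class AlignmentError(RamanChemoError):
    """Spectra do not share a common wavenumber grid."""


class ExtrapolationError(RamanChemoError):
    """A target grid point lies outside the source spectrum's range."""


class MissingFileError(RamanChemoError):
    """A manifest row points to a file that does not exist."""


class EmptyRangeError(RamanChemoError):
    """Truncation left no grid points."""


class NormalizationError(RamanChemoError):
    """A spectrum with zero euclidean norm cannot be vector-normalized."""


class ConvergenceError(RamanChemoError):
    """Iterative baseline fitting failed to converge.

    Attributes
    ----------
    last_baseline : numpy.ndarray or None
        Baseline from the final iteration, for inspection.
    """

    def __init__(self, message, last_baseline=None):
        super().__init__(message)
        self.last_baseline = last_baseline


class MissingReferenceError(RamanChemoError):
    """The requested reference spectrum/group is absent from the dataset."""


class FoldError(RamanChemoError):
    """A leave-one-out fold would empty or degenerate a class."""


class UndefinedMetricError(RamanChemoError):
    """A classification metric is undefined (e.g., empty positive class)."""


class BandRangeError(RamanChemoError):
    """A band window does not overlap the spectral grid."""


class ConfigError(RamanChemoError):
    """The pipeline configuration file is invalid or incomplete."""
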