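"""Exception hierarchy shared by all excispec modules.

Exit-code mapping used by the CLI:
  ConfigurationError -> 2, DataFormatError -> 3, FitError -> 4.
"""


class ExcispecError(Exception):
    """Base class for all excispec errors."""


class ConfigurationError(ExcispecError):
    """Invalid configuration, parameter or precondition violation."""


class DataFormatError(ExcispecError):
    """Malformed input file or inconsistent data object."""


class IncompatibleGridError(DataFormatError):
    """Two curves/spectra are not defined on the same grid."""


class FitError(ExcispecError):
    """Fitting could not be carried out."""


class DegenerateDataError(FitError):
    """Data carry no usable signal (e.g. all-zero counts)."""


class InvalidStateError(FitError):
    """Operation requires a converged fit (or other prior state)."""


class UndefinedReferenceError(ExcispecError):
    """A relative quantity was requested against a zero reference."""


class UnidentifiableMixtureError(FitError):
    """Mixture decomposition is degenerate (identical references)."""
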