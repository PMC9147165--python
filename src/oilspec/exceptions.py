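"""Exception hierarchy.

All package errors derive from :class:`OilspecError`; the grid runner
converts the ``DegenerateInputError`` branch into ``status='degenerate'``
records instead of crashing.
"""


class OilspecError(Exception):
    """Base class for all oilspec errors."""


class IrregularGridError(OilspecError):
    """Wavenumber axis is not uniformly spaced ("irregular grid")."""


class InconsistentMetadataError(OilspecError):
    """Spectra with mixed techniques/resolutions in one container or file."""


class SpectraParseError(OilspecError):
    """Malformed spectra CSV (non-numeric cell, bad header, ...)."""


class DegenerateInputError(OilspecError):
    """Input on which a statistic is undefined; recoverable at grid level."""


class DegenerateSpectrumError(DegenerateInputError):
    """All-zero or constant spectrum row ("degenerate spectrum")."""


class EmptySelectionError(DegenerateInputError):
    """Variable selection retained no features ("empty selection")."""


class UninformativeResponseError(DegenerateInputError):
    """Constant dependent variable ("uninformative response")."""
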