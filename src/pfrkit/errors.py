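"""Exception hierarchy shared across the package."""


class PfrkitError(Exception):
    """Base class for all package errors."""


class ParameterError(PfrkitError, ValueError):
    """A configuration or acquisition parameter violates its constraints."""


class InputError(PfrkitError, ValueError):
    """User-supplied data (arrays, masks, tables, files) is invalid."""


class GeometryError(PfrkitError, ValueError):
    """The requested phantom geometry does not fit the imaging volume."""


class NoConcavePeakError(PfrkitError, ValueError):
    """The quadratic fitted to a derivative curve opens upward: no filling peak."""


class DegenerateDataError(PfrkitError, ValueError):
    """A statistic is undefined for the supplied data (zero variance, |r| = 1, ...)."""
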