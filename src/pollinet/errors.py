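"""Exception hierarchy shared across the package."""


class PollinetError(Exception):
    """Base class for all package errors."""


class DataFormatError(PollinetError):
    """A file or frame does not match the documented CSV contract."""


class ValidationError(PollinetError):
    """Cross-table consistency violated (orphan species, bad sums, ...)."""


class FocalMissingError(PollinetError):
    """The focal pollinator is absent from a site where it is required."""


class UndefinedOverlapError(PollinetError):
    """Niche overlap requested for a species with zero recorded visits."""


class DegenerateHullError(PollinetError):
    """Convex hull is not computable for a community (too few / coplanar points)."""


class ModelFitError(PollinetError):
    """A regression model could not be fit (singular design, non-convergence)."""
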