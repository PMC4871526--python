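"""Exception hierarchy for apseg.

All domain errors derive from :class:`APSegError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid inputs or parameters.
"""


class APSegError(Exception):
    """Base class for all apseg errors."""


class InvalidInputError(APSegError, ValueError):
    """An input array/image violates a precondition (shape, dtype, values)."""


class InvalidParameterError(APSegError, ValueError):
    """A numeric parameter is outside its valid range."""


class InvalidSeedError(APSegError, ValueError):
    """Seed indices are out of range, overlapping, or missing."""


class InvalidLabelError(APSegError, ValueError):
    """Unknown segmentation label (only 'f' and 'b' exist)."""


class InvalidGeometryError(APSegError, ValueError):
    """Viewfinder frame geometry is degenerate for the given image size."""


class InvalidSpecError(APSegError, ValueError):
    """A synthetic phantom specification cannot be rasterized."""


class EmptyMaskError(APSegError, ValueError):
    """A binary mask has no foreground pixels where at least one is required."""


class EmptyPriorError(APSegError, ValueError):
    """The thresholded shape prior has empty support."""


class PriorFormatError(APSegError):
    """A serialized shape prior file is corrupt or has an unknown layout."""


class SolverError(APSegError, RuntimeError):
    """The sparse linear solve failed or did not reach the residual target."""
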