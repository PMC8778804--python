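"""Exception hierarchy.

All package errors derive from :class:`CTInertiaError` so callers can catch
one base class; most also derive from the closest builtin (``ValueError``,
``IOError``) so untyped callers still get sensible behaviour.
"""


class CTInertiaError(Exception):
    """Base class for all package errors."""


class DimensionMismatchError(CTInertiaError, ValueError):
    """Arrays/slices that must share a shape do not."""


class EmptyInputError(CTInertiaError, ValueError):
    """An input collection that must be nonempty is empty."""


class MetadataError(CTInertiaError, ValueError):
    """Required spatial metadata is missing or inconsistent."""


class AmbiguousSeriesError(CTInertiaError, ValueError):
    """A directory holds more than one image series."""


class EmptyRoiError(CTInertiaError, ValueError):
    """A region of interest contains no voxel centers."""


class DegenerateFitError(CTInertiaError, ValueError):
    """A regression or decomposition has no unique solution."""


class InsufficientDataError(CTInertiaError, ValueError):
    """Fewer data points than the operation requires."""


class BracketError(CTInertiaError, ValueError):
    """A root/target is not bracketed by the supplied bounds."""


class DomainError(CTInertiaError, ValueError):
    """An argument lies outside the mathematical domain of the operation."""


class FitError(CTInertiaError, RuntimeError):
    """A nonlinear fit failed to converge."""


class NoOscillationError(CTInertiaError, ValueError):
    """A trace contains no detectable oscillation above the noise floor."""


class SymmetryError(CTInertiaError, ValueError):
    """A matrix required to be symmetric is not."""


class RankError(CTInertiaError, ValueError):
    """Input points are too degenerate (collinear/coincident) for the fit."""


class LayoutError(CTInertiaError, ValueError):
    """Generated geometry overlaps or falls outside the volume."""


class ConfigError(CTInertiaError, ValueError):
    """A run configuration failed validation."""
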