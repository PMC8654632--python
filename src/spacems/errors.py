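"""Exception hierarchy for spacems.

All errors raised by the library derive from :class:`SpaceMSError` so callers
can catch everything from one base class while still distinguishing geometry
problems from anatomy or input problems.
"""


class SpaceMSError(Exception):
    """Base class for all spacems errors."""


class MaskIOError(SpaceMSError):
    """A volume could not be read or written."""


class DimensionalityError(SpaceMSError):
    """A volume is not 3-D (or 4-D with a singleton fourth axis)."""


class GeometryError(SpaceMSError):
    """An affine is missing, singular, or otherwise unusable."""


class SpaceMismatchError(SpaceMSError):
    """Two masks that must share a space do not (affine or shape differ)."""


class AnatomyError(SpaceMSError):
    """An anatomical reference mask (SMA, brainstem) is empty."""


class EmptyInputError(SpaceMSError):
    """An operation that needs at least one voxel/position received none."""


class DegenerateNeuraxisError(SpaceMSError):
    """The SMA and brainstem centres of mass coincide; no axis is defined."""


class LesionLookupError(SpaceMSError, KeyError):
    """A lesion ID is not present in a label map."""


class DomainError(SpaceMSError, ValueError):
    """A numeric argument is outside the mathematical domain of a metric."""
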