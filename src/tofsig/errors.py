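"""Exception hierarchy used across the package.

Every tofsig-raised error derives from :class:`TofsigError` so callers can
catch the whole family in one clause while still distinguishing input
problems from numerical degeneracies.
"""


class TofsigError(Exception):
    """Base class for all errors raised by tofsig."""


class InputError(TofsigError):
    """A file or argument could not be read or understood."""


class MetadataError(InputError):
    """Required image metadata (e.g. voxel spacing) is missing or invalid."""


class ConsistencyError(TofsigError):
    """Internally inconsistent data, e.g. a mesh whose per-vertex scalar
    array does not match its vertex count."""


class DegenerateInputError(TofsigError):
    """Mathematically degenerate input, e.g. zero variance where a
    standard deviation is required."""


class EmptySurfaceError(TofsigError):
    """An iso-value outside the data range yields no surface."""


class EmptyResultError(TofsigError):
    """An operation removed everything, e.g. component cleanup dropped
    every connected component."""


class OutOfBoundsError(TofsigError):
    """A sample position lies outside the voxel-center bounding box;
    no extrapolation is performed."""


class ParameterError(TofsigError):
    """A parameter value outside its valid domain (e.g. offset d <= 0)."""


class GeometryError(TofsigError):
    """A synthetic geometry does not fit inside its volume."""
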