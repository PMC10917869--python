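"""Exception hierarchy shared across the package."""


class VBGradientError(Exception):
    """Base class for all package errors."""


class InputError(VBGradientError, ValueError):
    """Invalid user-supplied data or parameters (CLI exit code 2)."""


class DegenerateGraphError(VBGradientError):
    """A graph operation cannot proceed, e.g. a zero-degree vertex in geig mode."""


class GraphConstructionError(VBGradientError):
    """A requested synthetic graph embedding is infeasible."""


class OutOfVolumeError(VBGradientError):
    """A surface vertex maps to a voxel index outside the volume grid."""


class SpatialMismatchError(InputError):
    """Volume, mask and surface metadata disagree (shape, affine, vertex count)."""


class NumericalError(VBGradientError):
    """An eigensolver or other numerical routine failed (CLI exit code 3)."""
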