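"""Exception types raised across the package."""


class CurvalignError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(CurvalignError):
    """A mesh file could not be parsed in the requested format."""


class OrientationError(MeshFormatError):
    """A mesh is not consistently orientable, so signed curvature is undefined."""


class DegenerateNeighborhoodError(CurvalignError):
    """A curvature neighborhood contains no mesh edges (radius too small)."""


class DegenerateConfigurationError(CurvalignError):
    """Point configuration too degenerate for a rigid fit (collinear/coincident)."""
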