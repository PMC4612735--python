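"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`RfasegError`
so callers (and the CLI) can catch one base class.
"""


class RfasegError(Exception):
    """Base class for all rfaseg errors."""


class InvalidParameterError(RfasegError, ValueError):
    """A parameter violates its documented range or invariant."""


class OutOfBoundsError(RfasegError, ValueError):
    """A seed or point lies outside the image volume."""


class DegenerateRegionError(RfasegError, ValueError):
    """A sampling region clipped to the volume contains no voxels."""


class StructuralError(RfasegError, ValueError):
    """Mismatched shapes between a node grid, template or network."""


class SolverError(RfasegError, RuntimeError):
    """The max-flow solver failed (overflow, malformed network)."""


class InfeasibleConstraintError(SolverError):
    """Boundary constraints contradict each other under the smoothness bound."""


class UnreachableConstraintError(RfasegError, ValueError):
    """A boundary constraint lies farther from the seed than the ray length."""


class SizeGuardError(RfasegError, ValueError):
    """A brute-force instance is too large to enumerate."""


class IncompleteCutError(RfasegError, ValueError):
    """A cut result lacks boundary points for some ray."""


class VoxelizationError(RfasegError, ValueError):
    """Surface voxelization failed (e.g. non-watertight mesh)."""


class ContourFormatError(RfasegError, ValueError):
    """A slice contour is open, self-intersecting or malformed."""


class GeometryError(RfasegError, ValueError):
    """Two masks or volumes do not share grid shape and spacing."""


class FormatError(RfasegError, ValueError):
    """An image file has an unknown format or a corrupt header."""


class PhantomSpecError(RfasegError, ValueError):
    """A phantom specification violates its intensity ordering or bounds."""
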