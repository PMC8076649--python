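"""Exception hierarchy for corridor-geometry and I/O failures.

Every error raised by this package derives from :class:`VSFError`, so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class VSFError(Exception):
    """Base class for all errors raised by the vsf package."""


class GeometryError(VSFError):
    """Base class for geometric degeneracies."""


class CollinearPointsError(GeometryError):
    """Three points meant to define a plane are (nearly) collinear."""


class DegenerateConfigurationError(GeometryError):
    """A point cloud admits no unique plane (e.g. all points collinear)."""


class ConvergenceError(GeometryError):
    """The plane optimizer failed to reach the required tolerance."""


class AmbiguousSideError(GeometryError):
    """A plane passes through the apex, so 'same side' is undefined."""


class RayParallelToPlaneError(GeometryError):
    """An apex ray never meets the target plane."""


class DegeneratePointError(GeometryError):
    """A point coincides with the apex (zero-length direction)."""


class DegenerateBasisError(GeometryError):
    """In-plane axes cannot be built (point coincides with the centroid)."""


class NotOnPlaneError(GeometryError):
    """A point that must lie on a plane is too far from it (strict mode)."""


class SelfIntersectionError(GeometryError):
    """A polygon expected to be simple intersects itself (strict mode)."""


class InvalidTriangleError(GeometryError):
    """Side lengths violate the triangle inequality beyond tolerance."""


class DegenerateMeshError(GeometryError):
    """A cone mesh cannot be built (apex on the base-ring plane)."""


class UnsupportedFormatError(VSFError):
    """An unknown mesh or table format was requested."""


class ConfigError(VSFError):
    """A simulation configuration parameter is out of range."""


class ParseError(VSFError):
    """An input file could not be parsed at all."""


class ValidationError(VSFError):
    """Parsed input violates the measurement-file invariants.

    The message aggregates every violation found, one per line, so a bad
    file is reported in full rather than failing on the first row.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("\n".join(self.problems))


class EmptyGroupError(VSFError):
    """Aggregation was requested over an empty collection of results."""
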