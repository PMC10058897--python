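"""Exception hierarchy for the wound3d pipeline."""


class Wound3DError(Exception):
    """Base class for all pipeline errors."""


class EmptyMesh(Wound3DError):
    """Mesh has no triangles where at least one is required."""


class Unreachable(Wound3DError):
    """No path exists between the requested graph nodes."""


class DegenerateNeighborhood(Wound3DError):
    """A curvature neighborhood has too few points (reported, value set to 0)."""


class DegenerateGeometry(Wound3DError):
    """Geometric quantity undefined (e.g. point coincides with camera center)."""


class TriangulationFailed(Wound3DError):
    """Surface triangulation left too many points isolated."""


class NoBoundary(Wound3DError):
    """Labeled mesh has no wound/non-wound boundary to extract."""


class OpenBoundary(Wound3DError):
    """The traced label boundary could not be closed into a loop."""


class DegenerateContour(Wound3DError):
    """Contour collapsed to (nearly) a single point; spline undefined."""


class AmbiguousInterior(Wound3DError):
    """No wound-labeled vertex strictly inside the contour to seed the cut."""


class SelfIntersectingLoop(Wound3DError):
    """A boundary loop self-intersects after projection to its PCA plane."""


class NotWatertight(Wound3DError):
    """Mesh has an edge not shared by exactly two triangles."""


class InputValidationError(Wound3DError):
    """Malformed input file or configuration (CLI exit code 2)."""
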