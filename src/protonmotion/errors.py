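"""Exception types raised across the planning pipeline."""


class ProtonMotionError(Exception):
    """Base class for all package errors."""


class GeometryError(ProtonMotionError):
    """Volumes or masks do not share a grid, or an object leaves the grid."""


class InvalidPhaseError(ProtonMotionError):
    """A respiratory phase label outside {0, 10, ..., 90} was requested."""


class CalibrationError(ProtonMotionError):
    """A HU-to-stopping-power calibration curve is malformed (non-monotone)."""


class UnsupportedGeometryError(ProtonMotionError):
    """A beam direction the parallel axis-aligned tracer cannot handle."""


class SOBPFlatnessError(ProtonMotionError):
    """SOBP weight optimization could not reach the requested plateau flatness."""

    def __init__(self, achieved: float, tolerance: float):
        self.achieved = achieved
        self.tolerance = tolerance
        super().__init__(
            f"SOBP plateau deviation {achieved:.4f} exceeds tolerance {tolerance:.4f}"
        )


class InfeasibleCompensatorError(ProtonMotionError):
    """Prescribed range is shallower than the distal target surface."""

    def __init__(self, deficit_cm: float):
        self.deficit_cm = deficit_cm
        super().__init__(
            f"range is {deficit_cm:.3f} cm short of the deepest distal target surface"
        )


class NormalizationError(ProtonMotionError):
    """Plan normalization is impossible (a target voxel receives zero dose)."""


class UndefinedCIError(ProtonMotionError):
    """Conformity index denominator is empty at the reference dose level."""
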