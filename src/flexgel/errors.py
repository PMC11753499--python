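"""Exception hierarchy for flexgel."""


class FlexgelError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(FlexgelError):
    """A distance or angle argument is outside its physical domain."""


class OverlapError(InvalidGeometryError):
    """Two beads coincide; the repulsive energy diverges."""


class GeometryError(FlexgelError):
    """Box geometry incompatible with the requested interaction range."""


class StabilityError(FlexgelError):
    """Integration became unstable (per-step displacement too large)."""


class DensityError(FlexgelError):
    """Random placement cannot satisfy the minimum-separation constraint."""


class CalibrationError(FlexgelError):
    """Bending-constant calibration target is unreachable."""


class EstimationError(FlexgelError):
    """An observable could not be estimated from the provided samples."""


class ConfigError(FlexgelError):
    """A run configuration document failed validation."""
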