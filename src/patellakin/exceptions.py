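"""Exception types shared across the pipeline stages."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(ValueError):
    """A cohort or optimizer configuration is inconsistent."""


class DegenerateGeometryError(ValueError):
    """A point cloud or landmark set is collinear/coplanar and cannot anchor a pose."""


class NearSingularRotationError(ValueError):
    """Rotation angle too close to pi for a stable matrix logarithm."""


class MalformedCycleError(ValueError):
    """A motion cycle whose peak-flexion frame lies at (or too close to) a boundary."""


class AlreadyMirroredError(ValueError):
    """Guard against applying the left-knee mirror map twice to the same trajectory."""
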