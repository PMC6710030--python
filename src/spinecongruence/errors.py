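"""Exception types shared across the package."""


class SpineCongruenceError(Exception):
    """Base class for all package errors."""


class InsufficientPointsError(SpineCongruenceError):
    """Cloud has fewer points than an operation requires."""


class DegenerateSampleError(SpineCongruenceError):
    """A minimal sample cannot define a unique model (collinear triple,
    coplanar quadruple, parallel normals).  RANSAC treats this as a spent
    iteration rather than an abort."""


class NoValidHypothesisError(SpineCongruenceError):
    """Every RANSAC iteration drew a degenerate sample."""


class CloudFormatError(SpineCongruenceError):
    """A point-cloud file could not be parsed."""


class ConfigError(SpineCongruenceError):
    """Invalid study configuration."""
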