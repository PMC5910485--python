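"""Exception hierarchy shared across the package."""


class PoredirectionError(Exception):
    """Base class for all package-specific errors."""


class MetadataError(PoredirectionError):
    """A required acquisition-metadata key is missing or invalid."""


class FormatError(PoredirectionError):
    """An input file is structurally unusable (empty stack, ragged frames...)."""


class DegenerateDesignError(PoredirectionError):
    """Calibration design cannot identify a line (e.g. one concentration)."""


class CalibrationQualityError(PoredirectionError):
    """Fitted calibration violates the monotone-increasing contract."""


class DegenerateROIError(PoredirectionError):
    """Cell mask too small to partition into three row groups."""


class ConfigurationError(PoredirectionError):
    """Simulation or analysis configuration violates an invariant."""


class SolverError(PoredirectionError):
    """Numerical solver produced an invalid state."""
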