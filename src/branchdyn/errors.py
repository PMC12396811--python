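"""Exception hierarchy for branchdyn."""


class BranchdynError(Exception):
    """Base class for all branchdyn errors."""


class InvalidParameterError(BranchdynError, ValueError):
    """A model or simulation parameter violates its domain (e.g. nonpositive rate)."""


class ConfigError(BranchdynError, ValueError):
    """A simulation or pipeline configuration is inconsistent (e.g. broken branch topology)."""


class WindowingError(BranchdynError, ValueError):
    """A trajectory segment cannot be windowed (too few cells for min_cells)."""


class DegenerateDataError(BranchdynError, ValueError):
    """Input data carry no usable signal (all-constant or all-zero samples)."""


class FormatError(BranchdynError, ValueError):
    """A file does not conform to the expected on-disk format."""


class AnnotationError(BranchdynError, ValueError):
    """A trajectory annotation is invalid or inconsistent with the count matrix."""


class NumericalError(BranchdynError, ArithmeticError):
    """A numerical routine failed to converge within its escalation budget."""
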