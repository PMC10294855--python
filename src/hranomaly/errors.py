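"""Exception hierarchy shared across the package."""


class HranomalyError(Exception):
    """Base class for package-specific failures."""


class ConfigurationError(HranomalyError, ValueError):
    """A configuration value violates its documented constraints."""


class CapacityError(HranomalyError, ValueError):
    """A series is too short to host the requested operation."""


class DegenerateSeriesError(HranomalyError, ValueError):
    """The input series is degenerate (e.g. zero variance) for this operation."""


class ModelFitError(HranomalyError, RuntimeError):
    """A statistical model could not be fitted."""


class DivergenceError(HranomalyError, RuntimeError):
    """Network training produced non-finite losses; try a lower learning rate."""
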