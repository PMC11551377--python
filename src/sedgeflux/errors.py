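"""Exception hierarchy shared across the package."""


class SedgefluxError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SedgefluxError, ValueError):
    """An input record or configuration violates its invariants."""


class ConfigError(SedgefluxError, ValueError):
    """A pipeline or file-format configuration is unusable."""


class FittingError(SedgefluxError, RuntimeError):
    """The temperature-response fit cannot be computed."""


class DegenerateDesignError(FittingError):
    """All usable observations share one leaf temperature; the slope is unidentifiable."""


class EmptyPeriodError(SedgefluxError, ValueError):
    """No flux steps fall inside the requested analysis period."""


class AlignmentError(SedgefluxError, ValueError):
    """Two series that must share timestamps do not."""
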