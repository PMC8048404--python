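"""Exception types shared across the package."""


class ScanforgeError(Exception):
    """Base class for all scanforge errors."""


class InvalidInputError(ScanforgeError, ValueError):
    """An input violates a documented precondition."""


class ConfigurationError(ScanforgeError, ValueError):
    """A configuration value is missing or inconsistent."""


class UndefinedCVError(ScanforgeError, ZeroDivisionError):
    """Coefficient of variation requested for a zero-mean group."""


class NotWatertightError(ScanforgeError, ValueError):
    """Enclosed volume requested for a mesh that does not bound a solid."""

    def __init__(self, message: str, surface_area: float | None = None):
        super().__init__(message)
        self.surface_area = surface_area
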