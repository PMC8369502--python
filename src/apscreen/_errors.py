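"""Exception types shared across the package."""


class FormatError(ValueError):
    """A trace or table file violates the documented on-disk format."""


class MappingError(ValueError):
    """Plate map and trace file disagree about which wells exist."""


class InvalidConfigError(ValueError):
    """A simulation or analysis configuration is internally inconsistent."""


class CalibrationError(RuntimeError):
    """Waveform calibration did not reach the requested tolerance.

    Carries the per-fraction residuals (ms) of the best candidate found.
    """

    def __init__(self, message: str, residuals_ms=None):
        super().__init__(message)
        self.residuals_ms = dict(residuals_ms or {})
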