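"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """A file does not conform to the expected dialect (missing columns, bad header)."""


class DataError(ValueError):
    """File parsed but its content violates a recording invariant (e.g. non-monotone time)."""


class CalibrationInfeasibleError(ValueError):
    """A patient lacks enough labeled ON/OFF decisions to fit an individual threshold.

    Mirrors the exclusion of patients whose recorded motor data were not
    sufficient to apply the validation protocol.
    """


class DegenerateSeparationError(ValueError):
    """Calibration classes share a single fluency value; no margin exists.

    Carries ``theta``, the common value, so callers can still fall back to it.
    """

    def __init__(self, message: str, theta: float):
        super().__init__(message)
        self.theta = theta
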