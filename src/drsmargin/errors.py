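"""Exception hierarchy for the DRS pipeline."""


class DRSError(Exception):
    """Base class for all drsmargin errors."""


class FormatError(DRSError):
    """A spectra file violates the DRSSPEC columnar format."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class CalibrationError(DRSError):
    """White/dark references cannot calibrate the sample (W - D <= 0 somewhere)."""


class CoverageError(DRSError):
    """A spectrum does not cover the wavelength range an operation needs."""


class DegenerateInputError(DRSError):
    """Input has no usable variation (e.g. constant spectrum passed to SNV)."""


class UndefinedMetricError(DRSError):
    """A metric (e.g. AUC) is undefined for the given labels."""
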