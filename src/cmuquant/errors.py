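"""Exception hierarchy shared across the package."""


class CmuQuantError(Exception):
    """Base class for all cmuquant errors."""


class CalibrationError(CmuQuantError):
    """A spike-in calibration could not be fitted (missing spike, bad fit)."""


class DegenerateDesignError(CalibrationError):
    """The calibration design matrix is singular (e.g. all spike abundances equal)."""


class InvalidCalibrationError(CalibrationError):
    """The fitted calibration is unusable (non-positive slope)."""


class ConfigurationError(CmuQuantError):
    """Invalid run configuration (empty catalog, missing path, bad option)."""


class MappingError(CmuQuantError):
    """Taxa could not be mapped onto a required resource (e.g. tree leaves)."""

    def __init__(self, message, taxa=()):
        super().__init__(message)
        self.taxa = tuple(taxa)


class UndefinedDiversityError(CmuQuantError):
    """A diversity quantity is undefined for the given profile(s)."""


class DesignError(CmuQuantError):
    """A statistical design requirement is violated (e.g. a single group)."""


class PairingError(CmuQuantError):
    """A paired analysis could not match samples (e.g. subject lacks baseline)."""


class ParseError(CmuQuantError):
    """An input file could not be parsed."""


class PipelineStageError(CmuQuantError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
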