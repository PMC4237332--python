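"""Exception hierarchy shared across the indicator pipeline."""


class PSRBError(Exception):
    """Base class for all package-specific errors."""


class EmptyMaskError(PSRBError, ValueError):
    """A spatial unit rasterized to zero cells (no cell center inside it)."""


class UndefinedMeanError(PSRBError, ValueError):
    """A zonal mean was requested over a mask with no valid (non-nodata) cells."""


class UndefinedRateError(PSRBError, ValueError):
    """A rate is undefined, e.g. annual forest loss with a zero 2000 baseline."""


class UndefinedScoreError(PSRBError, ValueError):
    """A score or index is undefined for an empty input set."""


class DataIntegrityError(PSRBError, ValueError):
    """Input data violates a structural invariant (cycles, bad reversals, ...)."""


class ConfigurationError(PSRBError, ValueError):
    """Invalid configuration: bad probabilities, missing quality coefficients, ..."""
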