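"""Exception hierarchy shared across the pipeline."""


class CrabRiskError(Exception):
    """Base class for all crabrisk errors."""


class ValidationError(CrabRiskError):
    """Input data violate a model contract (negative biomass, bad fraction, ...)."""


class FormatError(CrabRiskError):
    """A file is structurally malformed (missing columns, unparseable values)."""


class ConfigurationError(CrabRiskError):
    """A scenario or run configuration is incomplete or inconsistent."""


class CalibrationError(CrabRiskError):
    """Calibration cannot identify a parameter from the supplied observations."""


class CalibrationWarning(UserWarning):
    """Calibration succeeded but produced values that violate a soft expectation."""
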