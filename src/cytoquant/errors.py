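"""Exception hierarchy for the cytometry quantification pipeline."""


class CytoQuantError(Exception):
    """Base class for all package errors."""


class FormatError(CytoQuantError):
    """An input file does not have the expected structure."""


class ValidationError(CytoQuantError, ValueError):
    """A value or configuration field violates its invariants."""


class ConfigurationError(CytoQuantError):
    """A configuration combination is unusable (e.g. missing reference)."""


class CalibrationInputError(CytoQuantError):
    """Bead data cannot support calibration (too few events, overlap)."""


class ComputationError(CytoQuantError):
    """A statistic is undefined for the given input (e.g. empty sample)."""
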