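"""Exception hierarchy for the isodiet pipeline.

All validation problems raise :class:`IsodietError` subclasses so that the CLI
can map them to exit code 2 while genuine bugs propagate normally.
"""


class IsodietError(Exception):
    """Base class for all isodiet validation and domain errors."""


class SchemaError(IsodietError):
    """A required column is missing or a cell fails to parse."""


class VocabularyError(IsodietError):
    """An analyte name is not in the controlled amino-acid vocabulary."""


class ConfigError(IsodietError):
    """A run configuration is malformed or references an unknown model."""


class DomainError(IsodietError):
    """A numeric argument violates its domain (negative SD, bad counts...)."""


class ReductionError(IsodietError):
    """A GC session cannot be reduced (missing norleucine peak, no bracket...)."""


class CalibrationError(IsodietError):
    """Too few standards to fit the nitrogen calibration line."""


class ModelSpecError(IsodietError):
    """A mixing-model specification cannot be assembled from the sources."""


class DegenerateSignalError(IsodietError):
    """Every source has zero concentration of a signal's carrier."""
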