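"""Exception hierarchy for the dicect pipeline.

Every stage raises a subclass of :class:`DicectError` carrying enough
context (the offending group key, column, or position) for a batch run to
report per-probe failures without dying globally.
"""


class DicectError(Exception):
    """Base class for all dicect errors."""


class SchemaError(DicectError):
    """A required column is missing or mis-typed in an input table."""


class ValidationError(DicectError):
    """Input data violate a structural invariant (monotone positions,
    ragged groups, duplicated keys, grid gaps, ...)."""


class PairingError(DicectError):
    """Edge pairing could not produce the expected number of edge pairs."""


class RangeError(DicectError):
    """An interval lies outside the probe, or is too small to summarize."""


class LabelingError(DicectError):
    """Segment labels required for a metric are missing."""


class CoverageError(DicectError):
    """A required time point or slice is absent from a series."""


class CalibrationError(DicectError):
    """Phantom calibration is degenerate (water and air indistinguishable)."""
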