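"""Exception hierarchy for dietrsm.

Every error raised by the public API derives from :class:`DietRSMError`,
so callers can catch one base class at pipeline boundaries.
"""


class DietRSMError(Exception):
    """Base class for all dietrsm errors."""


class InvalidFactorError(DietRSMError):
    """A factor definition is unusable (e.g. non-positive half-range)."""


class InvalidDesignError(DietRSMError):
    """A requested experimental design is structurally impossible."""


class DimensionError(DietRSMError):
    """Level vectors do not match the number of factors."""


class RepresentationError(DietRSMError):
    """Actual-unit and coded-unit quantities were mixed."""


class ConversionError(DietRSMError):
    """Model representation conversion lacks factor metadata."""


class SingularDesignError(DietRSMError):
    """The model basis is rank-deficient on the supplied design points."""


class InsufficientDataError(DietRSMError):
    """Too few design points to estimate the full second-order model."""


class DegenerateAnchorError(DietRSMError):
    """Desirability anchors coincide, leaving the ramp undefined."""


class IncompleteInputError(DietRSMError):
    """A scenario response has no value or no model supplied."""


class UndefinedRatioError(DietRSMError):
    """A ratio endpoint was requested with a zero denominator."""


class SpecificationError(DietRSMError):
    """A surface slice specification is inconsistent (factor both fixed and free)."""


class ConfigError(DietRSMError):
    """A pipeline configuration file is malformed."""
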