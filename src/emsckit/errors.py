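"""Exception hierarchy.

Validation problems (bad files, bad arguments, degenerate inputs) derive
from :class:`ValidationError`; an ill-posed least-squares model that the
caller did not explicitly force raises :class:`IllPosedError`. The CLI maps
these onto exit codes 2 and 3 respectively.
"""


class EMSCError(Exception):
    """Base class for all errors raised by emsckit."""


class ValidationError(EMSCError, ValueError):
    """Invalid input: file contents, arguments, or degenerate data."""


class ParseError(ValidationError):
    """A delimited-text file could not be parsed."""


class AxisError(ValidationError):
    """Wavenumber axis violates its invariants (non-monotone, duplicates...)."""


class RegionError(ValidationError):
    """A spectral-region selection produced no channels or is malformed."""


class ExtrapolationError(ValidationError):
    """Interpolation target lies outside the source axis range."""


class ModelError(ValidationError):
    """EMSC model specification is inconsistent with the data."""


class DegenerateConstituentError(ModelError):
    """A constituent spectrum is (numerically) zero or lies in the model span."""


class NoVariationError(ModelError):
    """Residuals carry no variation; nothing to extract by PCA."""


class NormalizationError(ValidationError):
    """A spectrum cannot be normalized (zero norm, non-positive peak...)."""


class DegenerateScenarioError(ValidationError):
    """A synthetic scenario cannot produce the structure it promises."""


class IllPosedError(EMSCError):
    """The least-squares design is rank deficient and force was not given."""


class NearZeroScalingError(EMSCError):
    """Multiplicative scaling b is (near) zero; division is not meaningful."""
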