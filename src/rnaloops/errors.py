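"""Exception hierarchy shared across the package."""


class RnaloopsError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(RnaloopsError):
    """A 1-based coordinate or interval falls outside its transcript."""


class SpecificationError(RnaloopsError):
    """A variant specification is internally inconsistent (e.g. overlapping deletions)."""


class FormatError(RnaloopsError):
    """A text file does not conform to the expected tabular/structure format."""


class SequenceError(RnaloopsError):
    """A nucleotide sequence contains characters outside the RNA alphabet."""


class StateError(RnaloopsError):
    """An operation was applied to a profile in the wrong processing state."""


class NormalizationError(RnaloopsError):
    """Normalization cannot be performed (too few values, non-positive factor)."""


class ScalingError(RnaloopsError):
    """Cross-sample scaling has no usable common positions."""


class ParameterError(RnaloopsError):
    """A numeric parameter is outside its admissible range."""


class DataError(RnaloopsError):
    """Input data violate a precondition (length mismatch, missing annotation)."""


class LayoutError(RnaloopsError):
    """A synthetic core layout is infeasible (overlapping stems, motif outside loop)."""


class FitError(RnaloopsError):
    """A nonlinear or log-log fit failed or is degenerate."""
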