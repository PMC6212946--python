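"""Exception hierarchy shared by all endoref modules."""


class EndorefError(Exception):
    """Base class for all errors raised by endoref."""


class FormatError(EndorefError):
    """Input file does not conform to the expected tabular layout."""


class ValidationError(EndorefError):
    """Input parsed but violates a data invariant (e.g. non-positive Cq)."""


class ScaleError(EndorefError):
    """Operation applied to a matrix on the wrong scale (counts vs log2)."""


class ParameterError(EndorefError):
    """A parameter is outside its admissible range."""


class InsufficientDataError(EndorefError):
    """Too few genes, samples or points for the requested computation."""


class ConsistencyError(EndorefError):
    """Inputs that must agree (gene sets, reference coverage) do not."""


class AlphabetError(EndorefError):
    """Sequence contains characters outside the allowed alphabet."""
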