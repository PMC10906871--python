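"""Exception hierarchy for smoothindex."""


class SmoothIndexError(Exception):
    """Base class for all smoothindex errors."""


class ShapeError(SmoothIndexError, ValueError):
    """A matrix or vector has an incompatible shape."""


class DegenerateMatrixError(SmoothIndexError, ValueError):
    """The connectivity matrix has no off-diagonal edges, so the
    seriation objective is undefined."""


class ConfigurationError(SmoothIndexError, ValueError):
    """An option value is outside its valid range or unrecognized."""


class NotFeedForwardError(SmoothIndexError, ValueError):
    """Raised when a Schur factorization does not yield a permutation
    matrix, i.e. the circuit is not permutation-similar to a
    triangular (purely feed-forward) form."""


class MatrixFormatError(SmoothIndexError, ValueError):
    """A matrix file could not be parsed into a square numeric matrix."""
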