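"""Exception hierarchy shared across the package."""


class KanoNeedsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(KanoNeedsError, ValueError):
    """Input violates a documented contract (bad code, unknown category, ...)."""


class UndefinedCoefficientError(KanoNeedsError, ZeroDivisionError):
    """Better/worse coefficient undefined: every response classified R or Q."""


class ReconstructionError(KanoNeedsError, ValueError):
    """Counts reconstructed from percentages do not sum to the stated n."""


class DegenerateTableError(KanoNeedsError, ValueError):
    """A contingency table has a zero expected count; collapse categories."""


class SingularMatrixError(KanoNeedsError, ValueError):
    """Correlation matrix is singular; remove redundant items."""
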