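"""Exception hierarchy for qtlmm."""


class QtlmmError(Exception):
    """Base class for all qtlmm errors."""


class PedigreeError(QtlmmError):
    """Structural problem in a pedigree (unknown parent, cycle, bad twin group)."""


class NotPSDError(QtlmmError):
    """A covariance matrix is not positive semi-definite within tolerance."""

    def __init__(self, message, min_eigenvalue=None):
        super().__init__(message)
        self.min_eigenvalue = min_eigenvalue


class AlignmentError(QtlmmError):
    """Identifiers in one input cannot be matched against another."""


class SpecError(QtlmmError):
    """A model specification (or spec file) is invalid."""


class DegenerateDataError(QtlmmError):
    """The data admit no meaningful fit (e.g. all-missing column)."""


class ConvergenceError(QtlmmError):
    """An optimisation failed after all restarts."""
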