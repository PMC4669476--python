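"""Exception hierarchy for the muscle-network pipeline."""


class MuscleNetError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MuscleNetError, ValueError):
    """A parameter is outside its valid range (e.g. band edge beyond Nyquist)."""


class InvalidInputError(MuscleNetError, ValueError):
    """Input data violate a contract (negative weights, mismatched grids, ...)."""


class DegenerateInputError(MuscleNetError, ValueError):
    """Input is degenerate for the requested operation (zero variance, all-zero)."""


class SingularFitError(MuscleNetError, ValueError):
    """Regression design matrix is rank deficient (collinear or constant channels)."""


class IncompleteDesignError(MuscleNetError, ValueError):
    """A repeated-measures table has missing subject x condition x component cells."""


class StudyFormatError(MuscleNetError, ValueError):
    """An on-disk study directory violates the documented layout."""
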