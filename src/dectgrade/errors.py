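"""Exception hierarchy shared across the pipeline."""


class DectGradeError(Exception):
    """Base class for all package-specific errors."""


class InvalidCompositionError(DectGradeError):
    """Material fractions or histologic percentages are inconsistent."""


class InvalidConfigError(DectGradeError):
    """A simulation or pipeline configuration violates its invariants."""


class DimensionMismatchError(DectGradeError):
    """Arrays that must be aligned (channels, masks) have different shapes."""


class EmptyRoiError(DectGradeError):
    """A region of interest contains no voxels."""


class MomentUndefinedError(DectGradeError):
    """A standardized moment is requested for a degenerate (constant) sample."""


class UndefinedConcordanceError(DectGradeError):
    """Concordance is undefined, e.g. for a constant test-retest vector."""


class InvalidPatternError(DectGradeError):
    """A histologic pattern name is not part of the grading scheme."""


class ConvergenceError(DectGradeError):
    """Iterative model fitting failed to converge."""


class FormatError(DectGradeError):
    """An input file does not conform to the expected on-disk format."""
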