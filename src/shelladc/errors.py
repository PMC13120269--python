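"""Exception hierarchy shared across the pipeline."""


class ShellADCError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(ShellADCError):
    """Image is not a 3D scalar volume."""


class GeometryError(ShellADCError):
    """Grids disagree (shape, spacing, or origin) or a construction leaves the grid."""


class EmptyMaskError(ShellADCError):
    """A mask that must contain voxels is empty."""


class ParameterError(ShellADCError):
    """An argument violates its documented domain."""


class ValidationError(ShellADCError):
    """A cohort table or rating matrix violates its schema."""


class InsufficientDataError(ShellADCError):
    """Too few observations (or a missing class) for the requested statistic."""


class UndefinedCorrelationError(ShellADCError):
    """Correlation requested on a constant vector."""


class SeparationError(ShellADCError):
    """Logistic fit abandoned because a predictor perfectly separates the outcome."""
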