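"""Exception hierarchy for the summedstates package."""


class SummedStatesError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SummedStatesError, ValueError):
    """Invalid generator or run configuration."""


class ValidationError(SummedStatesError, ValueError):
    """A data container violates its contract (shape, labels, finiteness)."""


class AlignmentError(SummedStatesError, ValueError):
    """Labels of two objects that must be combined do not match."""


class DegeneratePatternError(SummedStatesError, ValueError):
    """A pattern or similarity input has zero variance where variance is required."""


class NormalizationError(SummedStatesError, ValueError):
    """Dual sum-normalization is undefined (zero row or column)."""


class CollinearityError(SummedStatesError, ValueError):
    """Predictors are collinear; the requested statistic is undefined."""


class SeparationError(SummedStatesError, RuntimeError):
    """Complete separation in a logistic fit; coefficients diverge."""


class SelectionError(SummedStatesError, RuntimeError):
    """Voxel selection could not retain any voxels at any threshold."""


class ExactFitError(SummedStatesError, ValueError):
    """Residual sum of squares is zero; the Gaussian BIC is minus infinity."""


class OverUnityWarning(UserWarning):
    """Disattenuated variance share exceeded 1 (sampling artifact)."""


class ReliabilityWarning(UserWarning):
    """Split-half reliability was non-positive and has been floored."""
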