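"""Exception hierarchy shared across the pipeline."""


class MegafaunaError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MegafaunaError):
    """A configuration value violates its documented constraints."""


class CongruenceError(MegafaunaError):
    """Gridded inputs disagree in shape or cell size."""


class GridSizeError(MegafaunaError):
    """A grid is too small for the requested stencil operation."""


class DegenerateInputError(MegafaunaError):
    """Input has no variation (all-zero scores, zero-variance vector, ...)."""


class CoverageError(MegafaunaError):
    """One or more regions own no valid raster cells."""

    def __init__(self, region_ids):
        self.region_ids = list(region_ids)
        super().__init__(f"regions with zero valid cells: {self.region_ids}")


class DesignError(MegafaunaError):
    """Model design matrix is rank deficient or columns mismatch."""


class ConvergenceError(MegafaunaError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        self.trace = trace or []
        super().__init__(message)


class NestingError(MegafaunaError):
    """Models passed to a nested test are not nested."""


class ComparisonError(MegafaunaError):
    """Fits compared by AIC do not share a response vector."""


class EstimationError(MegafaunaError):
    """Spatial model estimation impossible (singular system)."""


class RangeError(MegafaunaError):
    """Prediction requested outside the fitted covariate range."""


class UndefinedProportionError(MegafaunaError):
    """Extinction proportion undefined: zero extinct and zero extant."""


class SparseCategoryError(MegafaunaError):
    """A categorical level has too few observations to analyse."""


class DomainError(MegafaunaError):
    """Value outside the mathematical domain of a transform."""
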