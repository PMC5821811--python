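"""Exception hierarchy shared across the package."""


class AvalanchesError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AvalanchesError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive branching ratio)."""


class InsufficientDataError(AvalanchesError, ValueError):
    """Too few observations to carry out the requested computation."""


class InfeasibleEmbeddingError(AvalanchesError, ValueError):
    """An avalanche with S < T cannot occupy T bins with >=1 spike each."""


class PlacementError(AvalanchesError, RuntimeError):
    """Not enough empty stretches in a raster to place the requested events."""


class NoPlateauError(AvalanchesError, RuntimeError):
    """No admissible cutoff interval passed the goodness-of-fit gate.

    Carries the best sub-threshold fit for diagnostics.
    """

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class RasterParseError(AvalanchesError, ValueError):
    """A raster file could not be parsed; the message names the offending line."""


class DegenerateFitError(AvalanchesError, ValueError):
    """A sample is degenerate (e.g. single-valued) so the model fit is undefined."""
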