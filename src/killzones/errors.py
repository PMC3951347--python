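"""Exception types shared across the package."""


class KillzonesError(ValueError):
    """Base class for domain errors raised by this package."""


class InsufficientPointsError(KillzonesError):
    """A point-pattern operation needs more points than were supplied."""


class DegenerateRegionError(KillzonesError):
    """The study region contains no raster cells / has no interior."""


class SamplingFailureError(KillzonesError):
    """The point-process intensity is numerically zero everywhere."""


class ExtractionError(KillzonesError):
    """A covariate buffer contained no usable raster cells."""


class DegenerateCovariateError(KillzonesError):
    """A covariate column is constant and cannot be standardized."""


class FitFailureError(KillzonesError):
    """The spatial regression likelihood could not be maximized."""


class CollinearityError(KillzonesError):
    """The regression design matrix is numerically singular."""
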