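"""Exception hierarchy shared across the package."""


class SuperFeltError(Exception):
    """Base class for all package errors."""


class OmicsFormatError(SuperFeltError):
    """Malformed omics table: duplicate IDs, bad shape, wrong header."""


class OmicsParseError(SuperFeltError):
    """Non-numeric or missing cell in a numeric omics table."""


class OmicsValidationError(SuperFeltError):
    """Values violate an omics-kind invariant (e.g. mutation not in {0,1})."""


class AlignmentError(SuperFeltError):
    """Sample alignment across omics layers is impossible (empty intersection)."""


class ConfigurationError(SuperFeltError):
    """Invalid or infeasible configuration object."""


class InsufficientDataError(SuperFeltError):
    """Too few samples for the requested statistic."""


class DegenerateCurveError(SuperFeltError):
    """Variance profile has no knee (collinear or constant)."""


class MaskMismatchError(SuperFeltError):
    """A feature mask refers to features absent from the target matrix."""


class TrainingError(SuperFeltError):
    """Training preconditions violated (e.g. single-class labels)."""


class DegenerateDensityError(SuperFeltError):
    """Density is flat or the input has no spread; no threshold exists."""
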