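"""Exception and warning hierarchy shared across the package."""


class QuenchLabError(Exception):
    """Base class for all quenchlab errors."""


class FormatError(QuenchLabError):
    """A file does not conform to the expected tabular layout."""


class DataError(QuenchLabError):
    """Parsed data violate a domain invariant (duplicates, nonpositive response, ...)."""


class DomainError(QuenchLabError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class FitError(QuenchLabError):
    """A regression cannot be performed (too few points, degenerate design)."""


class AssemblyError(QuenchLabError):
    """A multi-spectrum structure cannot be assembled (e.g. missing reference)."""


class CalibrationError(QuenchLabError):
    """A standard curve cannot be calibrated."""


class ComparisonError(QuenchLabError):
    """Two summaries are not comparable (mismatched concentration ladders)."""


class ConditioningError(QuenchLabError):
    """A linear system is rank-deficient on the working grid."""


class ConfigError(QuenchLabError):
    """A run configuration is invalid (unknown keys, out-of-range values)."""


class QuenchLabWarning(UserWarning):
    """Base class for all quenchlab warnings."""


class DegeneratePeakWarning(QuenchLabWarning):
    """Peak detection on a flat spectrum."""


class PeakTieWarning(QuenchLabWarning):
    """Two or more equal maxima; the smaller wavelength was returned."""


class EnhancementWarning(QuenchLabWarning):
    """Fitted Stern-Volmer slope is negative: enhancement, not quenching."""


class DroppedPointWarning(QuenchLabWarning):
    """Points violating a fit precondition were dropped before fitting."""


class InterceptWarning(QuenchLabWarning):
    """Free-intercept Stern-Volmer fit strayed from the theoretical intercept of 1."""


class NegativeRateWarning(QuenchLabWarning):
    """An assay rate or power came out negative; reported unclipped."""


class CalibrationQualityWarning(QuenchLabWarning):
    """Trolox standard curve r-squared below the quality threshold."""
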