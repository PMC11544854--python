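"""Exception hierarchy for the OCT burn-score pipeline."""


class OctBurnError(Exception):
    """Base class for all package-specific errors."""


class GradingError(OctBurnError):
    """A feature grading is invalid."""


class IncompleteGradingError(GradingError):
    """A required score item is missing from a grading."""


class GradeRangeError(GradingError):
    """A score item carries a value outside its allowed range."""


class InvalidScoreError(OctBurnError):
    """A burn score outside 0-6 was supplied."""


class EmptyCohortError(OctBurnError):
    """A cohort-level statistic was requested on zero records."""


class CohortValidationError(OctBurnError):
    """A cohort table or record violates the schema."""


class ConfigError(OctBurnError):
    """A configuration object or file is invalid."""


class PhantomSpecError(OctBurnError):
    """A phantom specification is invalid."""


class SurfaceNotFoundError(OctBurnError):
    """The skin surface could not be recovered from a volume."""
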