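"""Exception hierarchy for crocvert.

All package-specific failures derive from :class:`CrocvertError` so callers
can catch one base class at pipeline boundaries.
"""


class CrocvertError(Exception):
    """Base class for all crocvert errors."""


class UnknownPositionError(CrocvertError):
    """A vertebral position label outside C2..Ca10 was supplied."""


class DuplicateMeasurementError(CrocvertError):
    """Two measurements were supplied for the same (specimen, position)."""


class InvalidMeasurementError(CrocvertError):
    """A measurement violates a basic constraint (e.g. non-positive CL)."""


class MissingPredictorError(CrocvertError):
    """A region/series predictor cannot be computed from the column.

    Carries the list of absent member positions in :attr:`missing`.
    """

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = list(missing)


class NoReferenceError(CrocvertError):
    """No conspecific or congeneric complete-series reference exists."""


class InsufficientDataError(CrocvertError):
    """Too few observations for a fit (n < 3)."""


class DegenerateFitError(CrocvertError):
    """Zero variance in x or y on the log scale; no line can be fitted."""


class NonInvertibleModelError(CrocvertError):
    """A power-law model with slope 0 cannot be inverted."""


class BootstrapFailureError(CrocvertError):
    """Too many degenerate bootstrap resamples; the redraw cap was exceeded."""


class NoAssessmentError(CrocvertError):
    """All suture states are unknown; maturity cannot be assessed."""


class NoMatureIndividualError(CrocvertError):
    """A species has no osteologically mature individual (species skipped)."""


class BoundUnavailableError(CrocvertError):
    """Maximum-TL bound requested for an indeterminate-maturity specimen."""


class ConfigError(CrocvertError):
    """A synthetic-world configuration violates a generator invariant."""
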