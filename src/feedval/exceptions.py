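"""Exception hierarchy for feedval.

All errors raised by the package derive from :class:`FeedvalError` so callers
can catch domain failures without masking programming errors.
"""


class FeedvalError(Exception):
    """Base class for all feedval errors."""


class InvalidCompositionError(FeedvalError):
    """A composition violates its invariants (e.g. DM outside (0, 100])."""


class InsufficientDataError(FeedvalError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(FeedvalError):
    """The statistic is undefined for these inputs (e.g. CV at mean 0)."""


class InvalidRecordError(FeedvalError):
    """A balance or digesta record violates its invariants."""


class InvalidSubstitutionError(FeedvalError):
    """The substitution fraction X must lie strictly between 0 and 1."""


class ConfigError(FeedvalError):
    """A configuration value is outside its documented range."""


class MarkerRecoveryError(FeedvalError):
    """Indigestible-marker concentration is zero or negative."""


class UndefinedDigestibilityError(FeedvalError):
    """Digestibility is undefined because the diet concentration is zero."""


class SchemaError(FeedvalError):
    """Required keys/columns are missing or mismatched between tables."""


class MissingTreatmentError(FeedvalError):
    """A diet has no observations to summarize."""


class DegenerateVariableError(FeedvalError):
    """A variable has zero variance; correlation is undefined."""


class CollinearityError(FeedvalError):
    """The design matrix is rank deficient."""


class DesignError(FeedvalError):
    """The requested crossover design is combinatorially infeasible."""


class FixtureLookupError(FeedvalError, KeyError):
    """Unknown packaged-table fixture name."""


class TruthInconsistencyError(FeedvalError):
    """Synthetic ground truth implies an impossible observation."""
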