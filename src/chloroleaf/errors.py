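"""Exception hierarchy for chloroleaf.

All errors raised by the library derive from :class:`ChloroleafError` so
callers can catch the whole family at once.  Specific subclasses mirror
the failure modes of the measurement pipeline: bad sensor readings,
features that cannot be computed, model/feature mismatches, malformed
assay inputs, and statistical preconditions that do not hold.
"""


class ChloroleafError(Exception):
    """Base class for all chloroleaf errors."""


class InvalidReadingError(ChloroleafError):
    """A sensor reading violates its physical constraints.

    Raised for negative channel intensities, non-finite values, or a
    non-positive clear channel (which makes normalization impossible).
    """


class UndefinedFeatureError(ChloroleafError):
    """A derived color feature cannot be computed (zero denominator).

    Carries the offending feature name in :attr:`feature`.
    """

    def __init__(self, feature: str, message: str | None = None):
        self.feature = feature
        super().__init__(message or f"feature {feature!r} is undefined for this input")


class EmptyInputError(ChloroleafError):
    """An operation that requires at least one element received none."""


class ModelMismatchError(ChloroleafError):
    """A model references a feature absent from the supplied feature vector."""


class InvalidAssayError(ChloroleafError):
    """Spectrophotometric assay input violates its constraints."""


class UndefinedCVError(ChloroleafError):
    """Coefficient of variation is undefined (zero mean)."""


class InsufficientReplicatesError(ChloroleafError):
    """Too few replicate measurements for the requested statistic."""


class CollinearityError(ChloroleafError):
    """The regression design matrix is rank deficient."""


class SampleSizeError(ChloroleafError):
    """Too few samples to fit the requested model."""


class ParameterError(ChloroleafError):
    """An operation parameter is out of its valid range."""


class ConfigError(ChloroleafError):
    """A generator or workflow configuration is invalid."""


class SchemaError(ChloroleafError):
    """A delimited-text table is missing required columns or malformed."""
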