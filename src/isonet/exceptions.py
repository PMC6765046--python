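"""Exception hierarchy for the isonet pipeline.

Every reader, feature extractor and pipeline stage raises a subclass of
:class:`IsonetError` so callers can catch pipeline problems without
swallowing programming errors.
"""


class IsonetError(Exception):
    """Base class for all errors raised by isonet."""


class ConfigurationError(IsonetError):
    """An invalid configuration value; the message names the offending field."""


class InputError(IsonetError):
    """Malformed or inconsistent on-disk input."""


class FeatureError(IsonetError):
    """A sequence descriptor could not be computed for a record."""


class NumericError(IsonetError):
    """A numeric contract was violated (e.g. a correlation outside [-1, 1])."""


class DataError(IsonetError):
    """A dataset does not satisfy the preconditions of a modelling step."""


class PipelineError(IsonetError):
    """An inconsistency between pipeline stages (e.g. a missing isoform)."""


class EvaluationError(IsonetError):
    """Model evaluation was requested on inputs it is not defined for."""
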