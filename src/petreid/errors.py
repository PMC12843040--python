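"""Exception hierarchy shared across the package."""


class PetreidError(Exception):
    """Base class for all package errors."""


class FormatError(PetreidError):
    """A file does not conform to the expected dialect (missing columns, bad header)."""


class ValidationError(PetreidError):
    """A data structure violates one of its declared invariants."""


class EmptyInputError(PetreidError):
    """An operation received an empty collection where at least one element is required."""


class CorruptionError(PetreidError):
    """A persisted artifact is truncated or inconsistent with its sidecar metadata."""


class ConfigError(PetreidError):
    """A configuration value is out of its admissible range."""


class SamplingError(PetreidError):
    """The balanced batch sampler cannot satisfy its P x K contract."""


class ProtocolError(PetreidError):
    """The verification-pair protocol cannot be instantiated on the given manifest."""


class UsageError(PetreidError):
    """An API was called with structurally incompatible arguments."""


class UndefinedMetricError(PetreidError):
    """A metric is undefined for the given inputs (e.g. single-class ROC)."""
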