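"""Exception hierarchy for imupos."""


class ImuposError(Exception):
    """Base class for all imupos errors."""


class RecordingParseError(ImuposError):
    """A recording file could not be parsed (names the offending line)."""


class SchemaError(ImuposError):
    """A file is readable but does not match the expected schema."""


class ValidationError(ImuposError):
    """An in-memory object violates its invariants."""


class ConfigError(ImuposError):
    """A configuration object (axis map, manifest, simulation config) is invalid."""


class ParameterError(ImuposError):
    """An operation received an out-of-range parameter."""


class DegenerateSignalError(ImuposError):
    """A signal is constant (or otherwise degenerate) where variation is required."""
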