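"""Exception types shared across the pipeline."""


class NicheRxError(Exception):
    """Base class for all package errors."""


class FormatError(NicheRxError, ValueError):
    """An on-disk file does not conform to its expected format."""


class ValidationError(NicheRxError, ValueError):
    """An in-memory object violates a data-model invariant."""


class ConfigError(NicheRxError, ValueError):
    """A configuration value is inconsistent or out of range."""
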