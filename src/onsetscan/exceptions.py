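"""Exception hierarchy shared across the pipeline."""


class OnsetScanError(Exception):
    """Base class for all package errors."""


class CohortFormatError(OnsetScanError):
    """An input table violates the expected format (missing column, bad value)."""


class DegenerateInputError(OnsetScanError):
    """Input is structurally unusable: constant vector, empty overlap, zero margin."""


class ConfigError(OnsetScanError):
    """A configuration object is internally inconsistent."""
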