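"""Exception hierarchy for the immunocarto pipeline."""


class ImmunocartoError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(ImmunocartoError):
    """Invalid configuration (bad sizes, unknown module names, bad flags)."""


class DataError(ImmunocartoError):
    """Malformed input data (NaNs, missing genes, duplicate ids)."""


class NormalizationError(ImmunocartoError):
    """Control probes missing or unusable for factor computation."""


class StatisticsError(ImmunocartoError):
    """Not enough samples / degenerate distributions for an estimate."""


class MappingError(ImmunocartoError):
    """Unknown treatment in the treatment→target-module map."""
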