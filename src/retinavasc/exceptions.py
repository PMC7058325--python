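"""Exception hierarchy; the CLI maps these to distinct exit codes."""


class RetinavascError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RetinavascError):
    """Invalid or inconsistent configuration values."""


class DataError(RetinavascError):
    """Malformed, misaligned or insufficient input data."""


class ModelError(RetinavascError):
    """Model misuse: untrained model, missing layers, bad checkpoint."""
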