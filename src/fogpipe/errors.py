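"""Exception hierarchy shared across the package."""


class FogpipeError(Exception):
    """Base class for all package errors."""


class FormatError(FogpipeError):
    """A file failed to parse or violated a format invariant.

    Carries enough location detail (file, line, gene/sample id) to find
    the offending record.
    """


class ValidationError(FogpipeError):
    """An in-memory object violated a domain invariant."""


class ConfigError(FogpipeError):
    """A pipeline configuration is incomplete or inconsistent."""
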