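"""Exception types shared across the package."""


class GearbeltError(Exception):
    """Base class for all package errors."""


class ParameterError(GearbeltError, ValueError):
    """A simulation or analysis parameter is non-finite or out of range."""


class GenerationError(GearbeltError, RuntimeError):
    """A synthetic renderer could not produce a valid frame."""


class AnalysisError(GearbeltError, RuntimeError):
    """An analysis stage could not produce a result from its input."""


class ConfigError(GearbeltError, ValueError):
    """A run configuration is malformed (unknown keys, bad types)."""


class FormatError(GearbeltError, ValueError):
    """An input file does not match the expected on-disk format."""
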