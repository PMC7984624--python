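"""Exception hierarchy shared across the package."""


class BedbenchError(Exception):
    """Base class for all package errors."""


class ParseError(BedbenchError):
    """A Eurostat-dialect file could not be parsed; message names the location."""


class AssemblyError(BedbenchError):
    """Region-year records could not be assembled from the input tables."""


class DomainError(BedbenchError, ValueError):
    """An operation was called outside its mathematical domain."""


class ConfigError(BedbenchError, ValueError):
    """An invalid configuration value (unknown mode, bad thresholds, ...)."""


class GenerationError(BedbenchError):
    """The synthetic generator could not realise the requested design."""
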