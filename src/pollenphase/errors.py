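"""Exception hierarchy shared across the package."""


class PollenPhaseError(Exception):
    """Base class for all errors raised by pollenphase."""


class ConfigError(PollenPhaseError, ValueError):
    """Invalid configuration or parameter value; message names the field."""


class InputError(PollenPhaseError, ValueError):
    """Invalid input data passed to an operation."""


class ParseError(InputError):
    """A file could not be parsed; message carries the line number where possible."""


class SchemaError(InputError):
    """A structured input violates the expected schema (columns, cell names, duplicates)."""
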