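"""Error taxonomy shared by the library and the CLI.

The CLI maps these onto distinct exit codes so callers can tell apart
missing files, malformed tables, and bad configuration.
"""


class JaspipeError(Exception):
    """Base class for package errors."""


class ConfigError(JaspipeError, ValueError):
    """Invalid configuration (bad parameter values, unknown keys/names)."""


class SchemaError(JaspipeError, ValueError):
    """Structurally invalid input data (missing columns, bad rows)."""
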