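"""Exception hierarchy shared across the pipeline.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class DimorphnetError(Exception):
    """Base class for all package errors."""


class ConfigError(DimorphnetError, ValueError):
    """Invalid configuration (bad parameter value, inconsistent settings)."""


class DataError(DimorphnetError, ValueError):
    """Invalid or malformed input data (files, tables, graphs)."""
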