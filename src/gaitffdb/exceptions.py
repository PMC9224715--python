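"""Exception hierarchy.

All errors derive from :class:`FFDBError` so callers can catch the package's
failures with a single clause. Configuration problems (bad parameters, wrong
columns) are distinguished from data problems (bad cell values, duplicate
identifiers) because the former are fixable in the config file and the latter
require looking at the input table.
"""


class FFDBError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FFDBError, ValueError):
    """A parameter, column name, or plan setting is invalid."""


class DataError(FFDBError, ValueError):
    """The input data violate a contract (duplicates, non-numeric cells, ...)."""


class BenchmarkError(FFDBError, RuntimeError):
    """The staged benchmark cannot proceed (e.g. every algorithm diverged)."""
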