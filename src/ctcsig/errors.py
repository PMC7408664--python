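"""Exception hierarchy shared across the pipeline stages."""


class CtcsigError(Exception):
    """Base class for all package errors."""


class ConfigError(CtcsigError):
    """Invalid configuration: bad simulation parameters, infeasible rules,
    missing negative controls when the negative-control filter is on, ..."""


class SchemaError(CtcsigError):
    """An input file is missing a required (mapped) column."""


class FormatError(CtcsigError):
    """An input file has malformed content (unparsable cell, dimension
    mismatch between a matrix and its companion detection matrix, ...)."""


class DataError(CtcsigError):
    """Structurally valid input that violates an analysis precondition
    (sample without CD45, one-class labels, empty survival table, ...)."""
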