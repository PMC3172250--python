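"""Exception types shared across the pipeline stages."""


class MirtimeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirtimeError, ValueError):
    """Invalid configuration value or unknown category/stage name."""


class InputError(MirtimeError, ValueError):
    """Structurally invalid input data (duplicates, missing columns, ...)."""


class ParseError(MirtimeError, ValueError):
    """Malformed record in an input file; message names the offending line."""


class CatalogError(MirtimeError, ValueError):
    """Invalid reference catalog (duplicate ids, empty category)."""


class StageError(MirtimeError, RuntimeError):
    """Pipeline stage failure; message names the stage and offending input."""
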