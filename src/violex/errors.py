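"""Exception hierarchy shared across the pipeline.

Two failure classes matter operationally: bad input data (exit code 1 in the
CLI) and bad configuration (exit code 2).  Everything else is a bug.
"""


class ViolexError(Exception):
    """Base class for all package-specific errors."""


class DataError(ViolexError):
    """Malformed, inconsistent or insufficient input data."""


class ConfigError(ViolexError):
    """Invalid configuration: bad dictionary, schema, hyper-parameters, paths."""
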