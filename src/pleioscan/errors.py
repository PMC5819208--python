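"""Exception hierarchy.

Three failure families are distinguished so callers (and the CLI) can
map them to exit codes: bad configuration, bad input data, and numerical
breakdown inside a computation.
"""


class PleioscanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PleioscanError):
    """A configuration value (column map, preset name, trait label) is wrong."""


class InputError(PleioscanError):
    """Input data violate a precondition (empty file, no SNP overlap, ...)."""


class NumericalError(PleioscanError):
    """A numerical routine failed (singular covariance, factorization failure)."""
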