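"""Exception hierarchy shared across the package.

The command-line layer maps these onto exit codes: configuration problems
exit 2, malformed or missing inputs exit 3, and numerical failures exit 4.
"""


class ConflandError(Exception):
    """Base class for all package errors."""


class ConfigError(ConflandError):
    """Invalid configuration: bad parameter values, unit mismatches, unknown keys."""


class InputError(ConflandError):
    """Malformed or missing input data."""


class FormatError(InputError):
    """A file does not parse, or its parts are mutually inconsistent."""


class SelectionError(InputError):
    """An atom selection does not resolve to exactly one atom."""


class SchemaError(InputError):
    """A tabular input violates its documented column schema."""


class NumericalError(ConflandError):
    """A computation cannot proceed (degenerate input, non-convergence)."""


class DegenerateInputError(NumericalError):
    """Input is formally valid but numerically degenerate (e.g. all-zero weights)."""
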