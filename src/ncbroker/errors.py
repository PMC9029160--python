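"""Exception hierarchy; exit codes map onto these classes in the CLI."""


class NcbrokerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NcbrokerError, ValueError):
    """Invalid or inconsistent user-supplied parameters (exit code 2)."""


class DataError(NcbrokerError, ValueError):
    """Input tables violate the data contract (exit code 3)."""


class StatisticalError(NcbrokerError, ValueError):
    """A statistical procedure cannot run (e.g. a group with < 2 samples)."""


class NumericalError(NcbrokerError, ArithmeticError):
    """An iterative numeric procedure failed to converge (exit code 4)."""
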