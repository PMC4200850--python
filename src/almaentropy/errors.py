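"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors exit 2 (handled by click),
:class:`DataError` exits 3, :class:`NumericalError` exits 4.
"""


class AlmaError(Exception):
    """Base class for all package-specific errors."""


class DataError(AlmaError):
    """Malformed or inconsistent input data (bad SMILES, bad CSV, bad labels)."""


class ParseError(DataError):
    """A SMILES string could not be parsed into a molecule."""


class ConfigurationError(AlmaError):
    """Invalid configuration, e.g. an element missing from the chi table."""


class NumericalError(AlmaError):
    """Numerical failure, e.g. a singular pooled covariance during the fit."""
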