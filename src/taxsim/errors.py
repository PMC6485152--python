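"""Exception hierarchy shared by all taxsim modules.

Every anticipated failure raises a :class:`TaxsimError` subclass so the CLI
can map validation problems to exit code 1 without leaking tracebacks.
"""


class TaxsimError(Exception):
    """Base class for all anticipated taxsim failures."""


class StructuralError(TaxsimError):
    """The taxonomy input is not a single-rooted tree (cycle, orphan, duplicate)."""


class CodeParseError(TaxsimError):
    """A concept code does not match the expected lexical pattern."""


class UnknownCodeError(TaxsimError, KeyError):
    """A concept code is not a node of the taxonomy."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return Exception.__str__(self)


class DomainError(TaxsimError, ValueError):
    """Inputs are outside the mathematical domain of an operation."""


class ConfigurationError(TaxsimError):
    """An invalid method selection, spec, or parameter combination."""
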