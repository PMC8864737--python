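"""Exception hierarchy shared across the package.

All input-validation failures derive from :class:`WormPathsError` so the
command-line layer can map them onto a single exit code.
"""


class WormPathsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(WormPathsError):
    """A tabular input file violates its documented dialect
    (missing column, duplicate key, empty required cell)."""


class CrossRefError(WormPathsError):
    """A reference (gene, metabolite, reaction, category) does not resolve."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = sorted(missing)


class RuleParseError(WormPathsError):
    """A gene rule string does not conform to the OR-of-AND grammar."""

    def __init__(self, message, text="", position=None):
        super().__init__(message)
        self.text = text
        self.position = position


class UnknownIdError(WormPathsError, KeyError):
    """Lookup of an id that is absent from the model or annotation set."""

    def __str__(self):  # KeyError quotes its arg; keep plain message
        return Exception.__str__(self)


class DomainError(WormPathsError, ValueError):
    """An argument is outside its mathematical or contractual domain."""


class ContractError(WormPathsError):
    """An operation was invoked on an object that violates its precondition."""
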