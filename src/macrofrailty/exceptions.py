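"""Exception hierarchy shared across the package.

``ValidationError`` covers user-facing input problems (bad schema, bad
config, constraint violations); the CLI maps it to exit code 2.
"""


class MacroFrailtyError(Exception):
    """Base class for all package errors."""


class ValidationError(MacroFrailtyError, ValueError):
    """Invalid input data or configuration."""


class SchemaError(ValidationError):
    """A table does not match its declared schema."""


class ConfigurationError(ValidationError):
    """An invalid generator or run configuration."""


class DomainError(MacroFrailtyError, ValueError):
    """A value outside the mathematical domain of an operation."""


class BalancedPanelError(ValidationError):
    """A panel operation required balance that the data lacks."""


class RankDeficientError(MacroFrailtyError, ValueError):
    """The regressor matrix is collinear after absorbing fixed effects."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "regressor matrix is rank deficient after absorbing fixed "
            f"effects; collinear columns: {self.columns}"
        )
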