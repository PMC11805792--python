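"""Exception hierarchy shared across the package."""


class IntersimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IntersimError, ValueError):
    """Invalid grid, profile, or run configuration."""


class DomainError(IntersimError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class SingularDesignError(IntersimError, ValueError):
    """Rank-deficient design matrix; carries cell/replicate context when known."""

    def __init__(self, message: str, cell_id=None, replicate=None, n=None):
        super().__init__(message)
        self.cell_id = cell_id
        self.replicate = replicate
        self.n = n
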