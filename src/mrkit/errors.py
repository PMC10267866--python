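"""Exception hierarchy shared across the package."""


class MRKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRKitError):
    """A setting, column map, or supplied resource is unusable."""


class ValidationError(MRKitError):
    """Input data violates a documented invariant.

    ``problems`` carries one human-readable message per offending row,
    each prefixed with its 1-based line number where applicable.
    """

    def __init__(self, message: str, problems: list[str] | None = None):
        super().__init__(message)
        self.problems = list(problems or [])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.problems:
            return base + "\n  " + "\n  ".join(self.problems)
        return base


class AnalysisError(MRKitError):
    """The analysis cannot proceed (e.g. no shared instruments)."""
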