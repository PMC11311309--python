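"""Exception hierarchy for freshshelf."""


class FreshShelfError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(FreshShelfError, ValueError):
    """Model parameters violate their domain (e.g. Nmax <= N0, mu_max <= 0)."""


class DegenerateSeriesError(FreshShelfError, ValueError):
    """A time series cannot support the requested fit (e.g. constant counts)."""


class LimitAlreadyExceededError(FreshShelfError, ValueError):
    """The acceptability limit is already crossed at t = 0."""


class LimitNeverReachedError(FreshShelfError, ValueError):
    """The acceptability limit lies beyond the model's asymptote."""


class UndefinedCorrelationError(FreshShelfError, ValueError):
    """Pearson correlation is undefined (zero variance in an input)."""


class UndefinedRSquaredError(FreshShelfError, ValueError):
    """R-squared is undefined because the total sum of squares is zero."""


class SchemaError(FreshShelfError, ValueError):
    """A tidy-CSV dataset violates the record schema.

    Carries a list of row-level problem descriptions in ``problems``.
    """

    def __init__(self, message: str, problems: list[str] | None = None):
        super().__init__(message)
        self.problems = problems or []

    def __str__(self) -> str:  # pragma: no cover - formatting only
        base = super().__str__()
        if self.problems:
            return base + "\n  " + "\n  ".join(self.problems)
        return base
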