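"""Exception hierarchy. Every error the pipeline can signal derives from
:class:`GestageError` so callers can catch package failures in one clause."""


class GestageError(Exception):
    """Base class for all package errors."""


class InvalidIntervalError(GestageError):
    """A dating source's date lies after the birth date."""


class MissingSourceError(GestageError):
    """A dating source required for the requested computation is absent."""


class DomainError(GestageError):
    """An argument is outside the operation's domain (e.g. negative GA)."""


class EmptyComparisonError(GestageError):
    """No pairwise-complete observations left for a comparison."""


class UndefinedKappaError(GestageError):
    """Chance agreement is 1 (single-cell marginals); kappa is undefined."""


class DegenerateTableError(GestageError):
    """A contingency table has an expected cell of zero."""


class ReferenceValidationError(GestageError):
    """A growth-reference table violates its invariants.

    Carries ``rows``: the offending (sex, week) keys with reasons.
    """

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = rows or []


class CohortSchemaError(GestageError):
    """A cohort file is unreadable or declares an unknown schema version."""


class JoinError(GestageError):
    """Record ids do not align between a cohort and its truth table."""


class StageError(GestageError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
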