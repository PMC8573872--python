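"""Exception hierarchy shared across the package."""
from __future__ import annotations


class AimPhenotypeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AimPhenotypeError):
    """A cohort table is missing a required column or has a malformed layout."""


class VocabularyError(AimPhenotypeError):
    """A value fell outside its controlled vocabulary."""


class ContractError(AimPhenotypeError):
    """A precondition of an operation was violated by the caller."""


class SequencingError(AimPhenotypeError):
    """Ballot rounds are not contiguous within a panel."""


class Rejection:
    """One rejected input row with its location and reason."""

    __slots__ = ("table", "row", "message")

    def __init__(self, table: str, row: int, message: str) -> None:
        self.table = table
        self.row = row  # 1-based data row number (header excluded)
        self.message = message

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Rejection(table={self.table!r}, row={self.row}, message={self.message!r})"

    def __str__(self) -> str:
        return f"{self.table} row {self.row}: {self.message}"


class CohortValidationError(AimPhenotypeError):
    """One or more cohort rows failed validation.

    Carries every rejection so that input row counts always reconcile:
    each row either loaded or appears here with its table and row number.
    """

    def __init__(self, rejections: list[Rejection]):
        self.rejections = rejections
        lines = "\n".join(str(r) for r in rejections[:20])
        more = "" if len(rejections) <= 20 else f"\n... and {len(rejections) - 20} more"
        super().__init__(f"{len(rejections)} row(s) failed validation:\n{lines}{more}")
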