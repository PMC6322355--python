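"""Data model and I/O for docking-score tables.

A score table holds one row per compound x target x receptor structure,
carrying the raw (dimensionless) docking score of that pose; more negative
means better predicted affinity. Tables are exchanged as comma-separated
text with a mandatory header::

    compound_id,compound_name,target_id,structure_id,score

Scores are stored at full input precision; typographic minus signs
(U+2212, as printed in journal tables) are normalized to ASCII before
parsing. Compound identity is ``compound_id`` alone; ``compound_name`` is
optional metadata.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError, ScoreParseError

REQUIRED_COLUMNS = ("compound_id", "compound_name", "target_id", "structure_id", "score")

#: translation table mapping typographic minus/dash variants to '-'
_MINUS_TRANSLATION = str.maketrans({"−": "-", "–": "-", "—": "-"})


def normalize_number_token(token: str) -> str:
    """Normalize a printed numeric token (Unicode minus, stray spaces)."""
    return token.strip().translate(_MINUS_TRANSLATION)


@dataclass(frozen=True)
class ScoreRecord:
    """One docking score: a compound posed into one structure of one target."""

    compound_id: str
    target_id: str
    structure_id: str
    score: float
    compound_name: str = ""

    def __post_init__(self):
        for attr in ("compound_id", "target_id", "structure_id"):
            if not getattr(self, attr):
                raise ValueError(f"{attr} must be nonempty")
        if not math.isfinite(self.score):
            raise ValueError(f"score must be finite, got {self.score!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.compound_id, self.target_id, self.structure_id)


class ScoreTable:
    """An ordered collection of :class:`ScoreRecord`.

    Row order is preserved as read. The table itself tolerates duplicate
    (compound, target, structure) keys so that :func:`validate_table` can
    report them; :func:`read_score_table` rejects duplicates at ingest.
    """

    def __init__(self, records: Iterable[ScoreRecord]):
        self.records: tuple[ScoreRecord, ...] = tuple(records)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, ScoreTable) and self.records == other.records

    def __repr__(self) -> str:
        return (f"ScoreTable({len(self.records)} records, "
                f"{len(self.compounds)} compounds, {len(self.targets)} targets)")

    @staticmethod
    def _ordered_unique(values: Iterable[str]) -> tuple[str, ...]:
        return tuple(dict.fromkeys(values))

    @property
    def compounds(self) -> tuple[str, ...]:
        """Distinct compound ids, in order of first appearance."""
        return self._ordered_unique(r.compound_id for r in self.records)

    @property
    def targets(self) -> tuple[str, ...]:
        """Distinct target ids, in order of first appearance."""
        return self._ordered_unique(r.target_id for r in self.records)

    @property
    def structures(self) -> tuple[str, ...]:
        return self._ordered_unique(r.structure_id for r in self.records)

    def duplicate_keys(self) -> list[tuple[str, str, str]]:
        """Keys occurring more than once, in first-appearance order."""
        seen: dict[tuple[str, str, str], int] = {}
        for r in self.records:
            seen[r.key] = seen.get(r.key, 0) + 1
        return [k for k, n in seen.items() if n > 1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.compound_id, r.compound_name, r.target_id, r.structure_id, r.score)
             for r in self.records],
            columns=list(REQUIRED_COLUMNS),
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_table`; empty report = clean table."""

    duplicate_keys: list[tuple[str, str, str]] = field(default_factory=list)
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)
    positive_scores: list[ScoreRecord] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (self.duplicate_keys or self.missing_pairs or self.positive_scores)


def read_score_table(path: str | Path, delimiter: str = ",") -> ScoreTable:
    """Read a delimited score table.

    Raises
    ------
    FormatError
        if a required header column is absent.
    ScoreParseError
        if a score field is non-numeric (message carries the line number).
    IntegrityError
        if the same (compound, target, structure) key occurs twice.
    """
    path = Path(path)
    records: list[ScoreRecord] = []
    seen: set[tuple[str, str, str]] = set()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        header = reader.fieldnames or []
        for column in REQUIRED_COLUMNS:
            if column not in header:
                raise FormatError(f"missing required column {column!r} in {path}")
        for row in reader:
            token = normalize_number_token(row["score"] or "")
            try:
                score = float(token)
            except ValueError:
                raise ScoreParseError(
                    f"non-numeric score {row['score']!r}", line=reader.line_num
                ) from None
            try:
                record = ScoreRecord(
                    compound_id=(row["compound_id"] or "").strip(),
                    compound_name=(row["compound_name"] or "").strip(),
                    target_id=(row["target_id"] or "").strip(),
                    structure_id=(row["structure_id"] or "").strip(),
                    score=score,
                )
            except ValueError as exc:
                raise ScoreParseError(str(exc), line=reader.line_num) from None
            if record.key in seen:
                raise IntegrityError(
                    f"duplicate score for (compound, target, structure) = {record.key}"
                )
            seen.add(record.key)
            records.append(record)
    return ScoreTable(records)


def write_score_table(table: ScoreTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a score table; scores serialized with full float precision."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(REQUIRED_COLUMNS)
        for r in table.records:
            writer.writerow(
                [r.compound_id, r.compound_name, r.target_id, r.structure_id, repr(r.score)]
            )


def validate_table(
    table: ScoreTable, required_targets: Sequence[str] | None = None
) -> ValidationReport:
    """Report duplicates, (compound, target) gaps and non-negative scores.

    ``missing_pairs`` enumerates compounds x ``required_targets`` with no
    record, in table compound order then given target order. The report is
    empty iff the table is complete, duplicate-free and all-negative.
    """
    report = ValidationReport(duplicate_keys=table.duplicate_keys())
    present = {(r.compound_id, r.target_id) for r in table.records}
    if required_targets is not None:
        targets = tuple(dict.fromkeys(required_targets))
        for compound in table.compounds:
            for target in targets:
                if (compound, target) not in present:
                    report.missing_pairs.append((compound, target))
    seen_positive: set[tuple[str, str, str]] = set()
    for r in table.records:
        if r.score >= 0 and r.key not in seen_positive:
            report.positive_scores.append(r)
            seen_positive.add(r.key)
    return report
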