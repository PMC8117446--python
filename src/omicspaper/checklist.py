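"""Narrow-format MIxS checklist table and its CSV serialization.

BioSamples property records are pivoted into a long-format table — one row
per (biosample, property) pair — which travels with the manuscript as its
supplementary CSV file.  The dialect is pinned so that the file is
reproducible byte for byte: comma delimiter, double-quote quoting with
quote doubling, UTF-8, LF line endings, and the fixed header
``biosample_accession,property_class,value,unit``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

from .parsers import BioSampleRecord

__all__ = [
    "ChecklistRow",
    "ChecklistTable",
    "MalformedTableError",
    "HEADER",
    "pivot",
    "write_csv",
    "read_csv",
]

HEADER = ("biosample_accession", "property_class", "value", "unit")


class MalformedTableError(ValueError):
    """Raised by :func:`read_csv` on rows that do not fit the schema."""


@dataclass(frozen=True)
class ChecklistRow:
    biosample_accession: str
    property_class: str
    value: str
    unit: str  # empty string when the property has no unit


@dataclass(frozen=True)
class ChecklistTable:
    rows: tuple[ChecklistRow, ...]

    def __len__(self) -> int:
        return len(self.rows)


def pivot(records: list[BioSampleRecord]) -> ChecklistTable:
    """Flatten BioSample property lists into a narrow-format table.

    Rows are grouped by biosample in input order, with properties in
    document order within each group; duplicate property classes are kept
    as distinct rows.  An empty record list yields a zero-row table.
    """
    rows: list[ChecklistRow] = []
    for record in records:
        for prop_class, value, unit in record.properties:
            rows.append(
                ChecklistRow(
                    biosample_accession=record.accession.value,
                    property_class=prop_class,
                    value=value,
                    unit=unit or "",
                )
            )
    return ChecklistTable(rows=tuple(rows))


def write_csv(table: ChecklistTable) -> str:
    """Serialize a table to CSV text in the pinned dialect (deterministic)."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=",", quotechar='"', lineterminator="\n")
    writer.writerow(HEADER)
    for row in table.rows:
        writer.writerow(
            [row.biosample_accession, row.property_class, row.value, row.unit]
        )
    return buf.getvalue()


def read_csv(text: str) -> ChecklistTable:
    """Parse CSV text back into a table; inverse of :func:`write_csv`.

    Raises
    ------
    MalformedTableError
        Missing/wrong header, or a row with the wrong number of fields
        (the message carries the 1-based row number).
    """
    reader = csv.reader(io.StringIO(text), delimiter=",", quotechar='"')
    try:
        header = next(reader)
    except StopIteration:
        raise MalformedTableError("row 1: missing header")
    if tuple(header) != HEADER:
        raise MalformedTableError(f"row 1: expected header {list(HEADER)}, got {header}")
    rows: list[ChecklistRow] = []
    for i, fields in enumerate(reader, start=2):
        if len(fields) != len(HEADER):
            raise MalformedTableError(
                f"row {i}: expected {len(HEADER)} fields, got {len(fields)}"
            )
        rows.append(ChecklistRow(*fields))
    return ChecklistTable(rows=tuple(rows))
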