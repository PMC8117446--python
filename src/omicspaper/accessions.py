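"""Classification and range expansion of INSDC-style accession identifiers.

The ENA metadata model keys every object (study, project, experiment,
sample, run) to a unique accession whose alphabetic prefix encodes both the
object type and the INSDC archive of first submission (E\\* = ENA, S\\* = SRA,
D\\* = DDBJ).  BioSamples identifiers use the SAM\\* prefixes and ArrayExpress
experiments the ``E-XXXX-n`` pattern.  Cross-reference blocks in study
documents frequently compress long accession lists into hyphenated ranges
such as ``ERX000001-ERX000123``; this module provides the grammar to
classify individual identifiers and to expand those ranges
deterministically.

Classification is total: any string maps to exactly one
:class:`Kind` (possibly :attr:`Kind.UNKNOWN`) and never raises on
unrecognized input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Kind",
    "Accession",
    "AccessionRange",
    "InvalidAccessionError",
    "MalformedRangeError",
    "RangeTooLargeError",
    "classify",
    "expand_range",
    "MAX_RANGE_SIZE",
]

#: Expanding a single hyphenated range beyond this many accessions is treated
#: as malformed link text rather than a legitimate cross-reference.
MAX_RANGE_SIZE = 10_000


class InvalidAccessionError(ValueError):
    """Raised for empty or whitespace-only identifier input."""


class MalformedRangeError(ValueError):
    """Raised for ranges mixing accession kinds or running backwards."""


class RangeTooLargeError(ValueError):
    """Raised when a range would expand past :data:`MAX_RANGE_SIZE` items."""


class Kind(str, Enum):
    STUDY = "study"
    PROJECT = "project"
    EXPERIMENT = "experiment"
    SAMPLE = "sample"
    BIOSAMPLE = "biosample"
    ARRAYEXPRESS = "arrayexpress"
    RUN = "run"
    UNKNOWN = "unknown"


# Public INSDC prefix conventions. Order matters only for readability; the
# prefix sets are disjoint. SAM* identifiers deliberately classify as
# biosample (not sample) so that they route to the BioSamples database arm
# of the pipeline rather than the ENA sample endpoint.
_PATTERNS: tuple[tuple[Kind, re.Pattern[str]], ...] = (
    (Kind.STUDY, re.compile(r"^(ERP|SRP|DRP)\d+$")),
    (Kind.PROJECT, re.compile(r"^(PRJEB|PRJNA|PRJDB)\d+$")),
    (Kind.EXPERIMENT, re.compile(r"^(ERX|SRX|DRX)\d+$")),
    (Kind.SAMPLE, re.compile(r"^(ERS|SRS|DRS)\d+$")),
    (Kind.BIOSAMPLE, re.compile(r"^(SAMEA|SAMN|SAMD)\d+$")),
    (Kind.RUN, re.compile(r"^(ERR|SRR|DRR)\d+$")),
    (Kind.ARRAYEXPRESS, re.compile(r"^E-[A-Z]{4}-\d+$")),
)

_SPLIT_SUFFIX = re.compile(r"^(.*?)(\d+)$")


@dataclass(frozen=True, order=True)
class Accession:
    """A classified identifier.

    Ordering is lexicographic on ``(value, kind)`` only so instances can live
    in sorted containers; numeric-aware ordering for range expansion uses
    :attr:`number` explicitly.
    """

    value: str
    kind: Kind

    @property
    def prefix(self) -> str:
        """Alphabetic (non-numeric-suffix) part, e.g. ``ERX`` or ``E-MTAB-``."""
        m = _SPLIT_SUFFIX.match(self.value)
        return m.group(1) if m else self.value

    @property
    def number(self) -> int | None:
        """Numeric suffix as an integer, or None if there is none."""
        m = _SPLIT_SUFFIX.match(self.value)
        return int(m.group(2)) if m else None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AccessionRange:
    """An inclusive range of same-kind accessions, ``start`` ≤ ``end``."""

    start: Accession
    end: Accession

    def __post_init__(self) -> None:
        if self.start.kind != self.end.kind or self.start.kind is Kind.UNKNOWN:
            raise MalformedRangeError(
                f"range endpoints differ in kind: {self.start.value}-{self.end.value}"
            )
        if self.start.prefix != self.end.prefix:
            raise MalformedRangeError(
                f"range endpoints differ in prefix: {self.start.value}-{self.end.value}"
            )
        s, e = self.start.number, self.end.number
        if s is None or e is None or e < s:
            raise MalformedRangeError(
                f"descending or non-numeric range: {self.start.value}-{self.end.value}"
            )

    def __len__(self) -> int:
        return self.end.number - self.start.number + 1  # type: ignore[operator]

    def expand(self) -> list[Accession]:
        """Materialize the range, preserving the start token's zero-padding."""
        if len(self) > MAX_RANGE_SIZE:
            raise RangeTooLargeError(
                f"range {self.start.value}-{self.end.value} expands to "
                f"{len(self)} accessions (cap {MAX_RANGE_SIZE})"
            )
        width = len(self.start.value) - len(self.start.prefix)
        prefix = self.start.prefix
        return [
            Accession(f"{prefix}{n:0{width}d}", self.start.kind)
            for n in range(self.start.number, self.end.number + 1)  # type: ignore[arg-type]
        ]


def classify(text: str) -> Accession:
    """Classify an identifier string into an :class:`Accession`.

    Total over non-empty input: unrecognized strings get kind UNKNOWN.

    Raises
    ------
    InvalidAccessionError
        If *text* is empty or whitespace-only.
    """
    value = text.strip()
    if not value:
        raise InvalidAccessionError("empty or whitespace-only accession")
    for kind, pattern in _PATTERNS:
        if pattern.match(value):
            return Accession(value, kind)
    return Accession(value, Kind.UNKNOWN)


def _expand_token(token: str) -> list[Accession]:
    """Expand one comma-separated token: a single accession or a range."""
    acc = classify(token)
    if acc.kind is not Kind.UNKNOWN:
        return [acc]
    # Try every hyphen as the range separator; ArrayExpress ids contain
    # hyphens themselves, so a naive single split would misparse E-MTAB ranges.
    for i, ch in enumerate(token):
        if ch != "-" or i == 0 or i == len(token) - 1:
            continue
        left, right = classify(token[:i]), classify(token[i + 1 :])
        if left.kind is not Kind.UNKNOWN and left.kind == right.kind:
            return AccessionRange(left, right).expand()
    raise MalformedRangeError(f"unrecognized accession or range token: {token!r}")


def expand_range(spec: str) -> list[Accession]:
    """Expand a range-or-list string into sorted, deduplicated accessions.

    *spec* may be a single accession (``"ERS5"``), a hyphenated range
    (``"ERX000001-ERX000003"``), or a comma-separated mix of both.  All
    tokens must expand to a single accession kind.  Output is in ascending
    numeric order with duplicates removed; zero-padding is preserved from
    each range's start token.

    Raises
    ------
    MalformedRangeError
        Mixed kinds, descending ranges, or unrecognizable tokens.
    RangeTooLargeError
        A single range wider than :data:`MAX_RANGE_SIZE`.
    """
    tokens = [t.strip() for t in spec.split(",") if t.strip()]
    if not tokens:
        raise MalformedRangeError(f"empty range specification: {spec!r}")
    accessions: list[Accession] = []
    for token in tokens:
        accessions.extend(_expand_token(token))
    kinds = {a.kind for a in accessions}
    if len(kinds) > 1:
        raise MalformedRangeError(
            f"mixed accession kinds in {spec!r}: {sorted(k.value for k in kinds)}"
        )
    unique = {a.value: a for a in accessions}
    return sorted(unique.values(), key=lambda a: (a.number or 0, a.value))
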