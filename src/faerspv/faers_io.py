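"""Readers and writers for FAERS-style quarterly ASCII tables.

FAERS publishes each quarter as a set of dollar-delimited text tables
(DEMO, DRUG, REAC, THER, OUTC) with a single header line and no quoting.
This module parses those files into :class:`RawTable` objects, validates
the minimal field set each table must carry, and normalises the several
date formats FAERS uses (4-, 6- or 8-digit strings) into
:class:`PartialDate` values that compare correctly at mixed precision.

Rows whose field count disagrees with the header are dropped and counted,
never silently repaired; the counts surface in a :class:`CurationLog` so
that report conservation (rows in = rows kept + rows dropped) can be
audited at every stage.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "DELIMITER",
    "MISSING",
    "TABLE_NAMES",
    "REQUIRED_FIELDS",
    "FaersParseError",
    "SchemaError",
    "LoadError",
    "PartialDate",
    "RawTable",
    "CurationLog",
    "parse_faers_date",
    "read_table",
    "write_table",
    "load_quarter",
]

DELIMITER = "$"

#: canonical marker for a missing field value
MISSING = ""

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "THER", "OUTC")

#: minimal field set each table must expose (matched case-insensitively)
REQUIRED_FIELDS: Mapping[str, tuple[str, ...]] = {
    "DEMO": (
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "wt", "wt_cod", "occp_cod", "occr_country",
    ),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "pt"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
    "OUTC": ("primaryid", "outc_cod"),
}

#: strings treated as missing after trimming/case-folding
_MISSING_TOKENS = frozenset({"", "null", "nan", "none", "unk", "unknown"})


class FaersParseError(ValueError):
    """A field value could not be parsed; carries the offending text."""

    def __init__(self, message: str, text: str = ""):
        super().__init__(message)
        self.text = text


class SchemaError(ValueError):
    """A table header lacks a required field."""


class LoadError(OSError):
    """A mandatory quarterly table file is absent."""


def normalize_missing(value: str) -> str:
    """Map blank/NULL-style tokens to the single missing marker."""
    v = value.strip()
    return MISSING if v.lower() in _MISSING_TOKENS else v


@functools.total_ordering
@dataclass(frozen=True)
class PartialDate:
    """A FAERS date at year, month or day precision.

    FAERS dates arrive as 4-, 6- or 8-digit strings.  Ordering uses the
    zero-padded digit string, so a year-precision date sorts before any
    full date in the same year — a deterministic total order that never
    imputes missing components.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self):
        if self.day is not None and self.month is None:
            raise FaersParseError("day without month", str(self))
        if self.month is not None and not 1 <= self.month <= 12:
            raise FaersParseError(f"month {self.month} out of range", str(self))
        if self.day is not None and not 1 <= self.day <= 31:
            raise FaersParseError(f"day {self.day} out of range", str(self))

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def sort_key(self) -> str:
        return self.as_string()

    def as_string(self) -> str:
        s = f"{self.year:04d}"
        if self.month is not None:
            s += f"{self.month:02d}"
        if self.day is not None:
            s += f"{self.day:02d}"
        return s

    def __lt__(self, other: "PartialDate") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.as_string()


def parse_faers_date(text: str) -> PartialDate | None:
    """Parse a 4/6/8-digit FAERS date string.

    Returns ``None`` for blank/NULL input.  Raises
    :class:`FaersParseError` for non-digit content, impossible
    components (month 13, day 32) or unexpected length.
    """
    t = normalize_missing(text)
    if t == MISSING:
        return None
    if not t.isdigit():
        raise FaersParseError(f"non-digit date {text!r}", text)
    if len(t) not in (4, 6, 8):
        raise FaersParseError(f"date length {len(t)} not in 4/6/8: {text!r}", text)
    year = int(t[:4])
    month = int(t[4:6]) if len(t) >= 6 else None
    day = int(t[6:8]) if len(t) == 8 else None
    try:
        return PartialDate(year, month, day)
    except FaersParseError as exc:
        raise FaersParseError(f"impossible date {text!r}: {exc}", text) from None


@dataclass
class CurationLog:
    """Line-oriented audit log; every entry records counts, never rows."""

    entries: list[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        self.entries.append(message)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("".join(e + "\n" for e in self.entries))


@dataclass
class RawTable:
    """One parsed quarterly table: ordered header plus text rows.

    Invariant: every row has exactly ``len(header)`` fields; header names
    are stored lower-cased and trimmed.
    """

    name: str
    header: list[str]
    rows: list[list[str]]
    n_dropped: int = 0

    def __post_init__(self):
        if self.name not in TABLE_NAMES:
            raise ValueError(f"unknown table name {self.name!r}")

    def column(self, field_name: str) -> list[str]:
        idx = self.header.index(field_name.lower())
        return [row[idx] for row in self.rows]

    def iter_dicts(self) -> Iterable[dict[str, str]]:
        for row in self.rows:
            yield dict(zip(self.header, row))

    def to_frame(self):
        """View as a pandas DataFrame of strings (missing already normalised)."""
        import pandas as pd

        return pd.DataFrame(self.rows, columns=self.header, dtype=str)

    @staticmethod
    def empty(name: str) -> "RawTable":
        return RawTable(name, [f.lower() for f in REQUIRED_FIELDS[name]], [])


def _check_schema(name: str, header: list[str], path: str | Path) -> None:
    missing = [f for f in REQUIRED_FIELDS[name] if f.lower() not in header]
    if missing:
        raise SchemaError(
            f"{path}: {name} header lacks required field(s) {', '.join(missing)}"
        )


def read_table(
    path: str | Path, expected_name: str, log: CurationLog | None = None
) -> RawTable:
    """Read one dollar-delimited FAERS table.

    The first line is the header.  Rows whose field count differs from
    the header's (e.g. a stray ``$`` in free text — the FAERS dialect has
    no quoting) are dropped and counted in *log*.  Field values are
    trimmed and blank/NULL tokens collapsed to the missing marker.
    """
    path = Path(path)
    if log is None:
        log = CurationLog()
    with open(path, encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline()
        if not header_line:
            raise SchemaError(f"{path}: empty file")
        header = [h.strip().lower() for h in header_line.rstrip("\r\n").split(DELIMITER)]
        _check_schema(expected_name, header, path)
        width = len(header)
        rows: list[list[str]] = []
        dropped = 0
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split(DELIMITER)
            if len(fields) != width:
                dropped += 1
                continue
            rows.append([normalize_missing(f) for f in fields])
    log.log(
        f"{path.name} ({expected_name}): rows_in={len(rows) + dropped} "
        f"rows_kept={len(rows)} rows_dropped={dropped}"
    )
    return RawTable(expected_name, header, rows, n_dropped=dropped)


def write_table(table: RawTable, path: str | Path) -> None:
    """Write a RawTable back to the dollar-delimited dialect (round-trips)."""
    lines = [DELIMITER.join(table.header)]
    lines.extend(DELIMITER.join(row) for row in table.rows)
    Path(path).write_text("".join(l + "\n" for l in lines))


def table_filename(name: str, quarter_tag: str) -> str:
    """Conventional file name, e.g. DEMO23Q4.txt for tag '23Q4'."""
    return f"{name}{quarter_tag}.txt"


def load_quarter(
    directory: str | Path, quarter_tag: str, log: CurationLog | None = None
) -> dict[str, RawTable]:
    """Load the five tables of one quarter.

    DEMO/DRUG/REAC are mandatory; a missing THER or OUTC file yields an
    empty table with a logged warning (some reports carry no therapy or
    outcome rows and small extracts may omit the files entirely).
    """
    directory = Path(directory)
    if log is None:
        log = CurationLog()
    tables: dict[str, RawTable] = {}
    for name in TABLE_NAMES:
        path = directory / table_filename(name, quarter_tag)
        if path.exists():
            tables[name] = read_table(path, name, log)
        elif name in ("THER", "OUTC"):
            log.log(f"warning: {path.name} missing; using empty {name} table")
            tables[name] = RawTable.empty(name)
        else:
            raise LoadError(f"mandatory table file missing: {path}")
    return tables
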