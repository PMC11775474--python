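"""Suspect-drug selection, name normalisation, ranking and ATC coding.

FAERS drug names are free text: brand names, international names and
misspellings all denote the same active ingredient.  A plain-text
:class:`NameMap` folds verbatim names onto ingredient names (with a
reserved ``EXCLUDE`` token for names too ambiguous to use), and an
:class:`AtcMap` assigns each ingredient its WHO ATC level-2 therapeutic
subgroup(s) (letter + two digits, e.g. ``L01`` antineoplastic agents).
Combination products are their own catalog entities — a fixed-dose
metformin+saxagliptin product is ranked and coded as itself, never split
into components.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .faers_io import CurationLog, MISSING, RawTable

__all__ = [
    "EXCLUDE_TOKEN",
    "DrugRecord",
    "NameMap",
    "AtcMap",
    "drug_records_from_table",
    "select_primary_suspect",
    "normalize_names",
    "rank_top_drugs",
    "map_atc2",
    "bundled_name_map",
    "bundled_atc_map",
]

#: NameMap value marking a verbatim name as unusably ambiguous
EXCLUDE_TOKEN = "EXCLUDE"

_ATC2_RE = re.compile(r"^[A-V]\d{2}$")

_ROLE_CODES = ("PS", "SS", "C", "I")


def normalize_name(name: str) -> str:
    return " ".join(name.strip().lower().split())


@dataclass(frozen=True)
class DrugRecord:
    """One DRUG row: a medication listed on a report version."""

    primaryid: str
    drug_seq: str
    role: str                  # PS / SS / C / I
    verbatim_name: str
    ingredient: str | None = None

    def __post_init__(self):
        if self.role not in _ROLE_CODES:
            raise ValueError(f"unknown drug role {self.role!r}")


@dataclass
class NameMap:
    """verbatim name -> ingredient name (normalised keys; a function)."""

    entries: dict[str, str]

    def __post_init__(self):
        self.entries = {
            normalize_name(k): v.strip() for k, v in self.entries.items()
        }
        if any(not v for v in self.entries.values()):
            raise ValueError("NameMap values must be non-blank")

    @classmethod
    def load(cls, path: str | Path) -> "NameMap":
        """Two-column (tab- or comma-delimited) text: verbatim, ingredient."""
        entries: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in re.split(r"\t|,", line, maxsplit=1)]
            if len(parts) != 2 or not parts[1]:
                raise ValueError(f"malformed NameMap line: {line!r}")
            key = normalize_name(parts[0])
            if key in entries and entries[key] != parts[1]:
                raise ValueError(f"NameMap maps {key!r} to two values")
            entries[key] = parts[1]
        return cls(entries)


@dataclass
class AtcMap:
    """ingredient -> set of ATC level-2 codes."""

    entries: dict[str, set[str]]

    def __post_init__(self):
        clean: dict[str, set[str]] = {}
        for ing, codes in self.entries.items():
            codes = {c.strip().upper() for c in codes}
            bad = [c for c in codes if not _ATC2_RE.match(c)]
            if bad:
                raise ValueError(f"not ATC level-2 codes: {bad}")
            if not codes:
                raise ValueError(f"empty ATC set for {ing!r}")
            clean[normalize_name(ing)] = codes
        self.entries = clean

    @classmethod
    def load(cls, path: str | Path) -> "AtcMap":
        """Two-column text (ingredient, ATC2), multiple rows per ingredient."""
        entries: dict[str, set[str]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in re.split(r"\t|,", line) if p.strip()]
            if len(parts) != 2:
                raise ValueError(f"malformed AtcMap line: {line!r}")
            entries.setdefault(parts[0], set()).add(parts[1])
        return cls(entries)

    def classes(self) -> set[str]:
        out: set[str] = set()
        for codes in self.entries.values():
            out |= codes
        return out


def _data_path(filename: str) -> Path:
    return Path(__file__).parent / "data" / filename


def bundled_name_map() -> NameMap:
    """The shipped brand/verbatim -> ingredient map (editable plain text)."""
    return NameMap.load(_data_path("name_map.tsv"))


def bundled_atc_map() -> AtcMap:
    """The shipped ingredient -> ATC level-2 map (editable plain text)."""
    return AtcMap.load(_data_path("atc2_map.tsv"))


def drug_records_from_table(drug: RawTable) -> list[DrugRecord]:
    records = []
    for rec in drug.iter_dicts():
        role = rec.get("role_cod", MISSING).upper()
        name = rec.get("drugname", MISSING)
        if rec.get("primaryid", MISSING) == MISSING or name == MISSING:
            continue
        if role not in _ROLE_CODES:
            continue
        records.append(
            DrugRecord(rec["primaryid"], rec.get("drug_seq", MISSING), role, name)
        )
    return records


def select_primary_suspect(records: Iterable[DrugRecord]) -> list[DrugRecord]:
    """Keep only primary-suspect (role PS) drug records."""
    return [r for r in records if r.role == "PS"]


def normalize_names(
    records: Iterable[DrugRecord],
    name_map: NameMap,
    log: CurationLog | None = None,
) -> list[DrugRecord]:
    """Fill ``ingredient`` from the name map; drop EXCLUDE-mapped records.

    Unmapped names pass through as their own (normalised) ingredient, so
    the operation is idempotent and never loses a drug merely for being
    absent from the map.
    """
    out: list[DrugRecord] = []
    n_excluded = 0
    for r in records:
        key = normalize_name(r.ingredient if r.ingredient else r.verbatim_name)
        mapped = name_map.entries.get(key, key)
        if mapped == EXCLUDE_TOKEN:
            n_excluded += 1
            continue
        out.append(replace(r, ingredient=normalize_name(mapped)))
    if log is not None and n_excluded:
        log.log(f"normalize_names: dropped {n_excluded} ambiguous-name record(s)")
    return out


def rank_top_drugs(
    records: Sequence[DrugRecord], case_ids: set[str], n: int
) -> list[tuple[str, int]]:
    """Top-*n* ingredients by distinct target-case report count.

    Each (ingredient, report) pair counts once.  Ties in count break
    alphabetically by ingredient so ranking is deterministic.
    """
    if n <= 0:
        raise ValueError(f"top-n must be positive, got {n}")
    seen: set[tuple[str, str]] = set()
    counts: dict[str, int] = {}
    for r in records:
        if r.primaryid not in case_ids:
            continue
        ing = r.ingredient if r.ingredient else normalize_name(r.verbatim_name)
        pair = (ing, r.primaryid)
        if pair in seen:
            continue
        seen.add(pair)
        counts[ing] = counts.get(ing, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def map_atc2(
    ingredient: str, atc_map: AtcMap, log: CurationLog | None = None
) -> set[str]:
    """ATC level-2 classes of an ingredient; empty set + warning if unmapped."""
    codes = atc_map.entries.get(normalize_name(ingredient))
    if codes is None:
        if log is not None:
            log.log(f"warning: no ATC level-2 mapping for {ingredient!r}")
        return set()
    return set(codes)
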