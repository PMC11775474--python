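"""SMQ-style case identification from reaction preferred terms.

Adverse events in FAERS are MedDRA preferred terms (PTs).  A case
definition here is a flat PT list — the narrow-scope style of a
Standardized MedDRA Query, where only terms highly specific for the
condition are retrieved.  Matching is exact after normalisation (trim +
case-fold); numeric MedDRA codes take precedence when both the record
and the definition carry them.  No substring or fuzzy matching: the
point of a narrow-scope search is specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .faers_io import MISSING, RawTable

__all__ = [
    "CaseDefinition",
    "ReactionRecord",
    "load_case_definition",
    "builtin_ahf_definition",
    "reactions_from_table",
    "find_case_ids",
]


def normalize_pt(term: str) -> str:
    return " ".join(term.strip().lower().split())


@dataclass(frozen=True)
class ReactionRecord:
    """One REAC row: a preferred term reported on one report version."""

    primaryid: str
    pt: str
    pt_code: int | None = None


@dataclass
class CaseDefinition:
    """A named set of PTs (and optionally their MedDRA codes) defining a condition."""

    name: str
    pt_terms: set[str] = field(default_factory=set)
    pt_codes: set[int] = field(default_factory=set)

    def __post_init__(self):
        self.pt_terms = {normalize_pt(t) for t in self.pt_terms if t.strip()}
        self.pt_codes = set(self.pt_codes)
        if not self.pt_terms and not self.pt_codes:
            raise ValueError(f"case definition {self.name!r} is empty")

    def matches(self, record: ReactionRecord) -> bool:
        # code match is authoritative when both sides carry codes
        if record.pt_code is not None and self.pt_codes:
            return record.pt_code in self.pt_codes
        return normalize_pt(record.pt) in self.pt_terms


def load_case_definition(path: str | Path, name: str | None = None) -> CaseDefinition:
    """Load a PT list file: one PT per line, optional tab + numeric MedDRA code.

    ``#`` comment lines and blank lines are ignored; duplicates collapse.
    """
    path = Path(path)
    terms: set[str] = set()
    codes: set[int] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        term = normalize_pt(parts[0])
        if term:
            terms.add(term)
        if len(parts) > 1 and parts[1].strip().isdigit():
            codes.add(int(parts[1].strip()))
    if not terms and not codes:
        raise ValueError(f"case definition file {path} contains no PTs")
    return CaseDefinition(name or path.stem, terms, codes)


#: the three acute-heart-failure PTs with their MedDRA codes
_AHF_PTS = (
    ("acute left ventricular failure", 10063081),
    ("acute right ventricular failure", 10063082),
    ("cardiac failure acute", 10007556),
)


def builtin_ahf_definition() -> CaseDefinition:
    """The three-PT acute heart failure definition (MedDRA-coded)."""
    return CaseDefinition(
        "acute heart failure",
        pt_terms={t for t, _ in _AHF_PTS},
        pt_codes={c for _, c in _AHF_PTS},
    )


def reactions_from_table(reac: RawTable) -> list[ReactionRecord]:
    records = []
    for rec in reac.iter_dicts():
        pt = rec.get("pt", MISSING)
        if rec.get("primaryid", MISSING) == MISSING or pt == MISSING:
            continue
        code = rec.get("pt_code", MISSING)
        records.append(
            ReactionRecord(
                rec["primaryid"], pt, int(code) if code.isdigit() else None
            )
        )
    return records


def find_case_ids(
    reactions: Iterable[ReactionRecord], definition: CaseDefinition
) -> set[str]:
    """Primaryids of reports carrying at least one matching PT (counted once)."""
    return {r.primaryid for r in reactions if definition.matches(r)}
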