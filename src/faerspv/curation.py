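"""Report-level curation: validity screening and case deduplication.

FAERS republishes a case every time it is updated, so one clinical case
(CASEID) may appear as several report versions (PRIMARYID).  Following
FDA guidance, curation keeps a single version per case: the one with the
most recent receipt date (FDA_DT), breaking receipt-date ties by the
larger PRIMARYID.  Before deduplication, structurally unusable reports
are removed — *incomplete* (missing primaryid/caseid) or *incorrect*
(unparseable receipt date, or age/weight outside human range after unit
conversion).

Detail rows (DRUG/REAC/THER/OUTC) of discarded versions are discarded
with them via :func:`filter_details`, so every downstream count is over
the deduplicated report set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .faers_io import (
    CurationLog,
    FaersParseError,
    PartialDate,
    RawTable,
    MISSING,
    parse_faers_date,
)

__all__ = [
    "AEReport",
    "CurationStats",
    "AGE_UNIT_YEARS",
    "reports_from_demo",
    "drop_invalid",
    "deduplicate",
    "filter_details",
]

#: multiplicative conversion of FAERS age unit codes to years.
#: Calendar-free divisors: 12 months, 52 weeks, 365.25 days, 8766 hours.
AGE_UNIT_YEARS = {
    "dec": 10.0,
    "yr": 1.0,
    "mon": 1.0 / 12.0,
    "wk": 1.0 / 52.0,
    "dy": 1.0 / 365.25,
    "hr": 1.0 / 8766.0,
}

_WEIGHT_UNIT_KG = {"kg": 1.0, "kgs": 1.0, "lbs": 0.45359237, "gms": 0.001}

_OCCUPATION_CODES = {
    "md": "physician",
    "ph": "pharmacist",
    "ot": "other health-professional",
    "hp": "other health-professional",
    "cn": "consumer",
    "lw": "lawyer",
}

MAX_AGE_YEARS = 150.0
MAX_WEIGHT_KG = 700.0


@dataclass(frozen=True)
class AEReport:
    """One curated case version from the DEMO table."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate | None
    event_dt: PartialDate | None = None
    age_years: float | None = None
    sex: str = "unknown"            # M / F / unknown
    weight_kg: float | None = None
    reporter_occupation: str = "unknown"
    country: str = "unknown"

    def primaryid_key(self):
        """Numeric ordering when the id parses as an integer, else lexicographic."""
        try:
            return (0, int(self.primaryid), "")
        except ValueError:
            return (1, 0, self.primaryid)


@dataclass
class CurationStats:
    """Counts reconciling input reports against curation drops."""

    n_input: int = 0
    n_dropped_incomplete: int = 0
    n_dropped_incorrect: int = 0
    n_dropped_duplicate: int = 0
    n_output: int = 0

    def check(self) -> None:
        assert self.n_input == (
            self.n_output
            + self.n_dropped_incomplete
            + self.n_dropped_incorrect
            + self.n_dropped_duplicate
        ), "curation counts do not reconcile"

    def merge(self, other: "CurationStats") -> "CurationStats":
        return CurationStats(
            n_input=self.n_input or other.n_input,
            n_dropped_incomplete=self.n_dropped_incomplete + other.n_dropped_incomplete,
            n_dropped_incorrect=self.n_dropped_incorrect + other.n_dropped_incorrect,
            n_dropped_duplicate=self.n_dropped_duplicate + other.n_dropped_duplicate,
            n_output=other.n_output,
        )

    def to_rows(self) -> list[dict]:
        return [
            {"category": "input", "count": self.n_input},
            {"category": "dropped_incomplete", "count": self.n_dropped_incomplete},
            {"category": "dropped_incorrect", "count": self.n_dropped_incorrect},
            {"category": "dropped_duplicate", "count": self.n_dropped_duplicate},
            {"category": "output", "count": self.n_output},
        ]


def _parse_age_years(age: str, age_cod: str) -> float | None:
    if age == MISSING:
        return None
    factor = AGE_UNIT_YEARS.get(age_cod.lower() or "yr")
    if factor is None:
        raise FaersParseError(f"unknown age unit {age_cod!r}", age_cod)
    return float(age) * factor


def _parse_weight_kg(wt: str, wt_cod: str) -> float | None:
    if wt == MISSING:
        return None
    factor = _WEIGHT_UNIT_KG.get(wt_cod.lower() or "kg", None)
    if factor is None:
        raise FaersParseError(f"unknown weight unit {wt_cod!r}", wt_cod)
    return float(wt) * factor


def reports_from_demo(demo: RawTable) -> list[AEReport]:
    """Parse DEMO rows into reports, deferring validity checks.

    Unparseable dates/ages/weights are carried as sentinel values so that
    :func:`drop_invalid` can count them as *incorrect* rather than this
    function raising mid-file.
    """
    reports: list[AEReport] = []
    for rec in demo.iter_dicts():
        parse_failed = False

        def attempt(fn, *args):
            nonlocal parse_failed
            try:
                return fn(*args)
            except (FaersParseError, ValueError):
                parse_failed = True
                return None

        fda_dt = attempt(parse_faers_date, rec.get("fda_dt", MISSING))
        event_dt = attempt(parse_faers_date, rec.get("event_dt", MISSING))
        age = attempt(_parse_age_years, rec.get("age", MISSING), rec.get("age_cod", ""))
        weight = attempt(_parse_weight_kg, rec.get("wt", MISSING), rec.get("wt_cod", ""))
        sex = rec.get("sex", MISSING).upper()
        del parse_failed  # individual sentinels (None) suffice for drop_invalid
        reports.append(
            AEReport(
                primaryid=rec.get("primaryid", MISSING),
                caseid=rec.get("caseid", MISSING),
                fda_dt=fda_dt,
                event_dt=event_dt,
                age_years=age,
                sex=sex if sex in ("M", "F") else "unknown",
                weight_kg=weight,
                reporter_occupation=_OCCUPATION_CODES.get(
                    rec.get("occp_cod", MISSING).lower(), "unknown"
                ),
                country=rec.get("occr_country", MISSING) or "unknown",
            )
        )
    return reports


def _is_incomplete(r: AEReport) -> bool:
    return r.primaryid == MISSING or r.caseid == MISSING


def _is_incorrect(r: AEReport) -> bool:
    if r.fda_dt is None:
        return True  # receipt date always present in valid FAERS reports
    if r.age_years is not None and not 0 <= r.age_years < MAX_AGE_YEARS:
        return True
    if r.weight_kg is not None and not 0 <= r.weight_kg < MAX_WEIGHT_KG:
        return True
    return False


def drop_invalid(
    reports: list[AEReport], log: CurationLog | None = None
) -> tuple[list[AEReport], CurationStats]:
    """Remove incomplete (missing ids) and incorrect (bad date/age/weight) reports."""
    stats = CurationStats(n_input=len(reports))
    kept: list[AEReport] = []
    for r in reports:
        if _is_incomplete(r):
            stats.n_dropped_incomplete += 1
        elif _is_incorrect(r):
            stats.n_dropped_incorrect += 1
        else:
            kept.append(r)
    stats.n_output = len(kept)
    stats.check()
    if log is not None:
        log.log(
            f"drop_invalid: input={stats.n_input} incomplete={stats.n_dropped_incomplete} "
            f"incorrect={stats.n_dropped_incorrect} kept={stats.n_output}"
        )
    return kept, stats


def deduplicate(
    reports: list[AEReport], log: CurationLog | None = None
) -> tuple[list[AEReport], CurationStats]:
    """Keep one version per caseid: latest FDA_DT, ties to the larger PRIMARYID.

    FDA_DT comparison is on the zero-padded digit string, so partial
    dates order deterministically against full ones.  Output order
    follows first appearance of each caseid in the input, making the
    operation idempotent and run-to-run stable.
    """
    stats = CurationStats(n_input=len(reports))
    best: dict[str, AEReport] = {}
    order: list[str] = []
    for r in reports:
        cur = best.get(r.caseid)
        if cur is None:
            best[r.caseid] = r
            order.append(r.caseid)
            continue
        key_new = (r.fda_dt.sort_key() if r.fda_dt else "", r.primaryid_key())
        key_cur = (cur.fda_dt.sort_key() if cur.fda_dt else "", cur.primaryid_key())
        if key_new > key_cur:
            best[r.caseid] = r
    kept = [best[cid] for cid in order]
    stats.n_dropped_duplicate = len(reports) - len(kept)
    stats.n_output = len(kept)
    stats.check()
    if log is not None:
        log.log(
            f"deduplicate: input={stats.n_input} duplicates={stats.n_dropped_duplicate} "
            f"kept={stats.n_output}"
        )
    return kept, stats


def filter_details(table: RawTable, surviving_primaryids: set[str]) -> RawTable:
    """Restrict a detail table to rows of surviving report versions."""
    idx = table.header.index("primaryid")
    rows = [row for row in table.rows if row[idx] in surviving_primaryids]
    return RawTable(table.name, table.header, rows, n_dropped=table.n_dropped)
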