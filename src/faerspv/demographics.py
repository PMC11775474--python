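"""Cohort characteristic tables and derived summary ratios.

Summaries follow the layout of clinical baseline tables: counts and
percentages by sex, age band, weight band, reporter occupation, top
reporting countries and seriousness outcomes.  Sex, age, weight and
occupation are true partitions of the cohort (counts sum to the total);
outcomes are multi-label — one report can be both hospitalised and fatal
— so outcome percentages may sum past 100%.

Percentages use half-up decimal rounding to one decimal, the convention
of printed clinical tables; derived ratios (male/female ratio, share of
patients ≥65 among known ages) round half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .curation import AEReport
from .faers_io import MISSING, RawTable
from .onset_weibull import round_half_up

__all__ = [
    "OutcomeRecord",
    "CharacteristicSummary",
    "outcomes_from_table",
    "summarize",
    "derived_ratios",
    "summary_from_counts",
    "load_published_counts",
]

AGE_BANDS = ("<18", "18-<65", "65-<85", ">=85", "Unknown")
WEIGHT_BANDS = ("<50", "50-<100", ">=100", "Unknown")

#: FAERS outcome codes -> table band
OUTCOME_LABELS = {
    "HO": "Hospitalization",
    "DE": "Death",
    "LT": "Life-threatening",
    "DS": "Disability",
    "OT": "Other Serious Outcome",
    "CA": "Other Serious Outcome",
    "RI": "Other Serious Outcome",
}

_HEALTHCARE = {"physician", "pharmacist", "other health-professional"}
_NON_HEALTHCARE = {"consumer", "lawyer"}


@dataclass(frozen=True)
class OutcomeRecord:
    primaryid: str
    outc_cod: str


@dataclass
class CharacteristicSummary:
    """Counts/percentages per band, grouped in sections, plus derived ratios."""

    total: int
    bands: dict[str, dict[str, tuple[int, float]]] = field(default_factory=dict)
    derived: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for section, band_map in self.bands.items():
            for band, (count, pct) in band_map.items():
                rows.append(
                    {"section": section, "band": band, "count": count,
                     "percentage": pct}
                )
        for name, value in self.derived.items():
            rows.append(
                {"section": "derived", "band": name, "count": pd.NA,
                 "percentage": value}
            )
        return pd.DataFrame(rows, columns=["section", "band", "count", "percentage"])


def outcomes_from_table(outc: RawTable) -> list[OutcomeRecord]:
    return [
        OutcomeRecord(rec["primaryid"], rec.get("outc_cod", MISSING).upper())
        for rec in outc.iter_dicts()
        if rec.get("primaryid", MISSING) != MISSING
    ]


def _pct(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total, 1)


def _age_band(age: float | None) -> str:
    if age is None:
        return "Unknown"
    if age < 18:
        return "<18"
    if age < 65:
        return "18-<65"
    if age < 85:
        return "65-<85"
    return ">=85"


def _weight_band(wt: float | None) -> str:
    if wt is None:
        return "Unknown"
    if wt < 50:
        return "<50"
    if wt < 100:
        return "50-<100"
    return ">=100"


def _occupation_band(occ: str) -> str:
    if occ in _HEALTHCARE:
        return "Healthcare professional"
    if occ in _NON_HEALTHCARE:
        return "Non-healthcare professional"
    return "Unknown"


def summarize(
    reports: Sequence[AEReport],
    outcome_records: Iterable[OutcomeRecord],
    case_ids: set[str],
    top_k_countries: int = 6,
) -> CharacteristicSummary:
    """Characteristic table for the cohort selected by *case_ids*."""
    cohort = [r for r in reports if r.primaryid in case_ids]
    if not cohort:
        raise ValueError("empty cohort: no reports match the case ids")
    total = len(cohort)

    def tally(keys: Iterable[str], order: Sequence[str]) -> dict[str, tuple[int, float]]:
        counts: dict[str, int] = {k: 0 for k in order}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        return {k: (c, _pct(c, total)) for k, c in counts.items()}

    sex = tally((r.sex if r.sex in ("M", "F") else "Unknown" for r in cohort),
                ("M", "F", "Unknown"))
    age = tally((_age_band(r.age_years) for r in cohort), AGE_BANDS)
    weight = tally((_weight_band(r.weight_kg) for r in cohort), WEIGHT_BANDS)
    occupation = tally(
        (_occupation_band(r.reporter_occupation) for r in cohort),
        ("Healthcare professional", "Non-healthcare professional", "Unknown"),
    )

    country_counts: dict[str, int] = {}
    for r in cohort:
        country_counts[r.country] = country_counts.get(r.country, 0) + 1
    top = sorted(
        ((c, n) for c, n in country_counts.items() if c != "unknown"),
        key=lambda cn: (-cn[1], cn[0]),
    )[:top_k_countries]
    top_names = {c for c, _ in top}
    others = sum(n for c, n in country_counts.items() if c not in top_names)
    country = {c: (n, _pct(n, total)) for c, n in top}
    country["Others"] = (others, _pct(others, total))

    # outcomes are multi-label: one band hit per distinct (report, band) pair
    cohort_ids = {r.primaryid for r in cohort}
    hit: set[tuple[str, str]] = set()
    for o in outcome_records:
        if o.primaryid in cohort_ids and o.outc_cod in OUTCOME_LABELS:
            hit.add((o.primaryid, OUTCOME_LABELS[o.outc_cod]))
    outcome_counts: dict[str, int] = {
        lbl: 0 for lbl in ("Hospitalization", "Death", "Other Serious Outcome",
                           "Life-threatening", "Disability")
    }
    reported = set()
    for pid, lbl in hit:
        outcome_counts[lbl] += 1
        reported.add(pid)
    outcome_counts["Unknown"] = total - len(reported)
    outcome = {k: (c, _pct(c, total)) for k, c in outcome_counts.items()}

    summary = CharacteristicSummary(
        total,
        {
            "sex": sex,
            "age": age,
            "weight": weight,
            "occupation": occupation,
            "country": country,
            "outcome": outcome,
        },
    )
    summary.derived = derived_ratios(summary)
    return summary


def derived_ratios(summary: CharacteristicSummary) -> dict[str, float]:
    """Male/female ratio and share of ≥65 patients among known-age reports.

    The elderly share uses only reports with a known age in the
    denominator; both values round half-up to 2 decimals.  A zero
    denominator yields NaN.
    """
    sex = summary.bands["sex"]
    age = summary.bands["age"]
    male = sex.get("M", sex.get("Male", (0, 0.0)))[0]
    female = sex.get("F", sex.get("Female", (0, 0.0)))[0]
    n_65plus = age["65-<85"][0] + age[">=85"][0]
    known_age = summary.total - age["Unknown"][0]
    out: dict[str, float] = {}
    out["male_female_ratio"] = (
        round_half_up(male / female, 2) if female else float("nan")
    )
    out["pct_65plus_known_age"] = (
        round_half_up(100.0 * n_65plus / known_age, 2) if known_age else float("nan")
    )
    return out


def summary_from_counts(
    total: int, bands: Mapping[str, Mapping[str, int]]
) -> CharacteristicSummary:
    """Build a summary from published band counts (no raw reports needed).

    Lets printed aggregate tables be re-analysed: percentages and derived
    ratios are recomputed from the counts with the same rounding rules.
    """
    summary = CharacteristicSummary(
        total,
        {
            section: {band: (n, _pct(n, total)) for band, n in band_map.items()}
            for section, band_map in bands.items()
        },
    )
    if "sex" in summary.bands and "age" in summary.bands:
        summary.derived = derived_ratios(summary)
    return summary


def load_published_counts(path: str | Path | None = None) -> CharacteristicSummary:
    """Load the bundled published heart-failure cohort counts as a summary.

    The bundled CSV carries the printed per-band counts of a published
    FAERS heart-failure cohort plus whole-database scalars (under section
    ``database``, not part of any partition).
    """
    if path is None:
        path = Path(__file__).parent / "data" / "published_table1_counts.csv"
    df = pd.read_csv(path)
    total = int(df[(df.section == "total") & (df.band == "total")]["count"].iloc[0])
    bands: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        if row.section == "total":
            continue
        bands.setdefault(row.section, {})[row.band] = int(row["count"])
    return summary_from_counts(total, bands)
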