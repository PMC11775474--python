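"""Synthetic FAERS-style quarter generator with known ground truth.

Emulates the structure of real quarterly extracts — five linked tables
keyed by PRIMARYID/CASEID, duplicate case versions distinguished by
FDA_DT, per-drug role codes with a primary-suspect subset, MedDRA-style
event terms, therapy start dates — while planting *known* quantities a
pipeline must recover:

* a drug-event odds multiplier ``r`` per drug: the target event is drawn
  with probability ``p1 = r·p0 / (1 − p0 + r·p0)``, whose odds are ``r``
  times the background odds ``p0/(1−p0)``, so the population reporting
  odds ratio of the drug equals ``r``;
* Weibull(α, β) onset intervals per drug, with dates derived backwards
  from a fixed anchor so every emitted date is parseable;
* demographic, country and outcome marginals shaped like a published
  heart-failure cohort table.

Duplicates perturb only FDA_DT and PRIMARYID (content is identical),
because case deduplication keys on exactly those fields.  All
randomness flows from ``SimConfig.seed``; the same seed yields
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .faers_io import RawTable, write_table, table_filename

__all__ = [
    "DrugSpec",
    "SimConfig",
    "GroundTruth",
    "plant_probability",
    "generate",
    "write_quarter",
    "DEFAULT_DRUGS",
]

_ANCHOR = date(2023, 6, 15)  # all synthetic event dates; starts precede it

#: a handful of brand names to exercise name normalisation
_BRANDS = {
    "rosiglitazone": "AVANDIA",
    "metformin": "GLUCOPHAGE",
    "atorvastatin": "LIPITOR",
    "ibuprofen": "ADVIL",
    "amlodipine": "NORVASC",
    "doxorubicin": "ADRIAMYCIN",
    "furosemide": "LASIX",
}

_BACKGROUND_PTS = (
    "Nausea", "Headache", "Dizziness", "Rash", "Fatigue",
    "Pyrexia", "Diarrhoea", "Vomiting", "Pruritus", "Insomnia",
)

_OUTCOME_CODES = ("HO", "DE", "OT", "LT", "DS", "")
_OUTCOME_PROBS = (0.407, 0.293, 0.195, 0.067, 0.004, 0.034)

_SEXES = ("M", "F", "")
_SEX_PROBS = (0.436, 0.465, 0.099)

_AGE_BANDS = ((1, 17), (18, 64), (65, 84), (85, 99), None)
_AGE_PROBS = (0.020, 0.308, 0.317, 0.044, 0.311)

_WEIGHT_BANDS = ((30, 49), (50, 99), (100, 150), None)
_WEIGHT_PROBS = (0.032, 0.206, 0.052, 0.710)

_OCCUPATIONS = ("MD", "PH", "OT", "CN", "LW", "")
_OCC_PROBS = (0.338, 0.100, 0.185, 0.307, 0.020, 0.050)

_COUNTRIES = ("US", "JP", "FR", "CA", "DE", "GB", "IT", "ES", "BR", "AU")
_COUNTRY_PROBS = (0.462, 0.069, 0.051, 0.039, 0.038, 0.032, 0.090, 0.080,
                  0.075, 0.064)


@dataclass(frozen=True)
class DrugSpec:
    """One simulated primary-suspect drug with its planted truth."""

    ingredient: str
    share: float          # marketing share: probability of being the PS drug
    r: float = 1.0        # planted target-event odds multiplier
    alpha: float = 191.02  # Weibull onset scale, days
    beta: float = 0.49     # Weibull onset shape

    def __post_init__(self):
        if self.share < 0 or self.r <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError(f"invalid drug spec {self}")


#: study-shaped defaults: one strongly associated drug (odds multiplier
#: mirroring the strongest published class signal) against background drugs,
#: all with early-failure onset kinetics.
DEFAULT_DRUGS: tuple[DrugSpec, ...] = (
    DrugSpec("rosiglitazone", 0.05, 12.51),
    DrugSpec("metformin", 0.15, 1.0),
    DrugSpec("atorvastatin", 0.20, 1.0),
    DrugSpec("ibuprofen", 0.30, 1.0),
    DrugSpec("amlodipine", 0.30, 1.0),
)


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the emulated study conditions."""

    n_cases: int = 10_000
    seed: int = 0
    drugs: tuple[DrugSpec, ...] = DEFAULT_DRUGS
    background_event_prob: float = 0.01     # target-event probability, r = 1
    duplicate_rate: float = 0.10            # cases emitted as >=2 versions
    tie_rate: float = 0.10                  # duplicates sharing the final FDA_DT
    target_pts: tuple[tuple[str, float], ...] = (
        ("Cardiac failure", 0.9),
        ("Cardiac failure acute", 0.1),
    )
    month_precision_rate: float = 0.05      # dates degraded to 6 digits
    missing_event_rate: float = 0.15
    missing_start_rate: float = 0.15
    concomitant_rate: float = 0.30          # extra role-C drug rows
    brand_name_rate: float = 0.30           # verbatim PS name uses a brand
    multi_outcome_rate: float = 0.05        # second outcome code on a report
    quarter_tag: str = "23Q4"

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not 0 < self.background_event_prob < 1:
            raise ValueError("background_event_prob must be in (0, 1)")
        for p in (self.duplicate_rate, self.tie_rate, self.month_precision_rate,
                  self.missing_event_rate, self.missing_start_rate,
                  self.concomitant_rate, self.brand_name_rate,
                  self.multi_outcome_rate):
            if not 0 <= p <= 1:
                raise ValueError("rates must be in [0, 1]")
        total_share = sum(d.share for d in self.drugs)
        if abs(total_share - 1.0) > 1e-9:
            raise ValueError(f"drug shares must sum to 1, got {total_share}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for end-to-end verification."""

    n_true_cases: int
    drugs: tuple[DrugSpec, ...]
    background_event_prob: float
    n_target_events: int = 0
    per_drug_case_count: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ingredient": d.ingredient,
                "share": d.share,
                "r": d.r,
                "alpha": d.alpha,
                "beta": d.beta,
                "n_cases": self.per_drug_case_count.get(d.ingredient, 0),
            }
            for d in self.drugs
        ]
        return pd.DataFrame(rows)


def plant_probability(r: float, p0: float) -> float:
    """Event probability whose odds are ``r`` times the background odds.

    p1 = r·p0 / (1 − p0 + r·p0).
    """
    if not 0 < p0 < 1:
        raise ValueError(f"background probability must be in (0, 1), got {p0}")
    if r <= 0:
        raise ValueError(f"odds multiplier must be positive, got {r}")
    return r * p0 / (1.0 - p0 + r * p0)


def _fmt_date(d: date, month_precision: bool) -> str:
    return f"{d.year:04d}{d.month:02d}" if month_precision else (
        f"{d.year:04d}{d.month:02d}{d.day:02d}"
    )


def generate(config: SimConfig) -> tuple[dict[str, RawTable], GroundTruth]:
    """Draw one synthetic quarter; returns the five tables plus ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = config.drugs

    # vectorised per-case draws (loop below only assembles strings)
    drug_idx = rng.choice(len(drugs), size=n, p=[d.share for d in drugs])
    p1 = np.array([plant_probability(d.r, config.background_event_prob)
                   for d in drugs])
    is_event = rng.random(n) < p1[drug_idx]
    tto_days = np.empty(n)
    for i, d in enumerate(drugs):
        mask = drug_idx == i
        tto_days[mask] = d.alpha * rng.weibull(d.beta, size=int(mask.sum()))
    tto_days = np.maximum(1, np.ceil(tto_days)).astype(int)

    sex = rng.choice(len(_SEXES), size=n, p=_SEX_PROBS)
    age_band = rng.choice(len(_AGE_BANDS), size=n, p=_AGE_PROBS)
    age_frac = rng.random(n)
    weight_band = rng.choice(len(_WEIGHT_BANDS), size=n, p=_WEIGHT_PROBS)
    weight_frac = rng.random(n)
    occ = rng.choice(len(_OCCUPATIONS), size=n, p=_OCC_PROBS)
    country = rng.choice(len(_COUNTRIES), size=n, p=_COUNTRY_PROBS)
    outcome = rng.choice(len(_OUTCOME_CODES), size=n, p=_OUTCOME_PROBS)
    extra_outcome = rng.random(n) < config.multi_outcome_rate
    extra_outcome_pick = rng.choice(5, size=n)

    target_pt_names = [t for t, _ in config.target_pts]
    target_pt_probs = [p for _, p in config.target_pts]
    target_pt = rng.choice(len(target_pt_names), size=n, p=target_pt_probs)
    n_bg_pts = rng.integers(1, 3, size=n)
    bg_pt = rng.integers(0, len(_BACKGROUND_PTS), size=(n, 2))

    fda_lag = rng.integers(10, 200, size=n)
    dup = rng.random(n) < config.duplicate_rate
    dup_tie = rng.random(n) < config.tie_rate
    dup_earlier = rng.integers(30, 300, size=n)
    ev_month = rng.random(n) < config.month_precision_rate
    st_month = rng.random(n) < config.month_precision_rate
    ev_missing = rng.random(n) < config.missing_event_rate
    st_missing = rng.random(n) < config.missing_start_rate
    concom = rng.random(n) < config.concomitant_rate
    concom_pick = rng.integers(0, len(drugs), size=n)
    brand = rng.random(n) < config.brand_name_rate

    demo_rows: list[list[str]] = []
    drug_rows: list[list[str]] = []
    reac_rows: list[list[str]] = []
    ther_rows: list[list[str]] = []
    outc_rows: list[list[str]] = []
    per_drug_count: dict[str, int] = {d.ingredient: 0 for d in drugs}
    n_target = 0

    for i in range(n):
        caseid = str(1_000_000 + i)
        dspec = drugs[drug_idx[i]]
        per_drug_count[dspec.ingredient] += 1
        event = bool(is_event[i])
        n_target += event

        event_date = _ANCHOR
        start_date = _ANCHOR - timedelta(days=int(tto_days[i]))
        fda_final = _ANCHOR + timedelta(days=int(fda_lag[i]))
        event_dt = "" if ev_missing[i] else _fmt_date(event_date, bool(ev_month[i]))
        start_dt = "" if st_missing[i] else _fmt_date(start_date, bool(st_month[i]))

        if _AGE_BANDS[age_band[i]] is None:
            age, age_cod = "", ""
        else:
            lo, hi = _AGE_BANDS[age_band[i]]
            years = lo + age_frac[i] * (hi - lo)
            if years < 2.0:  # infants reported in months, exercising conversion
                age, age_cod = str(int(max(1, round(years * 12)))), "MON"
            else:
                age, age_cod = str(int(years)), "YR"
        if _WEIGHT_BANDS[weight_band[i]] is None:
            wt, wt_cod = "", ""
        else:
            lo, hi = _WEIGHT_BANDS[weight_band[i]]
            wt, wt_cod = str(int(lo + weight_frac[i] * (hi - lo))), "KG"

        versions = [(caseid + "2", fda_final)]
        if dup[i]:
            earlier = (fda_final if dup_tie[i]
                       else fda_final - timedelta(days=int(dup_earlier[i])))
            versions.insert(0, (caseid + "1", earlier))

        for primaryid, fda_date in versions:
            demo_rows.append([
                primaryid, caseid, _fmt_date(fda_date, False), event_dt,
                age, age_cod, _SEXES[sex[i]], wt, wt_cod,
                _OCCUPATIONS[occ[i]], _COUNTRIES[country[i]],
            ])
            verbatim = (_BRANDS.get(dspec.ingredient, dspec.ingredient.upper())
                        if brand[i] else dspec.ingredient.upper())
            drug_rows.append([primaryid, "1", "PS", verbatim])
            if concom[i]:
                other = drugs[concom_pick[i]].ingredient.upper()
                drug_rows.append([primaryid, "2", "C", other])
            if event:
                reac_rows.append([primaryid, target_pt_names[target_pt[i]]])
            for k in range(int(n_bg_pts[i])):
                reac_rows.append([primaryid, _BACKGROUND_PTS[bg_pt[i, k]]])
            ther_rows.append([primaryid, "1", start_dt])
            codes = [_OUTCOME_CODES[outcome[i]]]
            if extra_outcome[i]:
                alt = _OUTCOME_CODES[extra_outcome_pick[i]]
                if alt and alt not in codes:
                    codes.append(alt)
            for code in codes:
                if code:
                    outc_rows.append([primaryid, code])

    tables = {
        "DEMO": RawTable("DEMO", ["primaryid", "caseid", "fda_dt", "event_dt",
                                  "age", "age_cod", "sex", "wt", "wt_cod",
                                  "occp_cod", "occr_country"], demo_rows),
        "DRUG": RawTable("DRUG", ["primaryid", "drug_seq", "role_cod",
                                  "drugname"], drug_rows),
        "REAC": RawTable("REAC", ["primaryid", "pt"], reac_rows),
        "THER": RawTable("THER", ["primaryid", "dsg_drug_seq", "start_dt"],
                         ther_rows),
        "OUTC": RawTable("OUTC", ["primaryid", "outc_cod"], outc_rows),
    }
    truth = GroundTruth(
        n_true_cases=n,
        drugs=drugs,
        background_event_prob=config.background_event_prob,
        n_target_events=int(n_target),
        per_drug_case_count=per_drug_count,
    )
    return tables, truth


def write_quarter(config: SimConfig, directory: str | Path) -> GroundTruth:
    """Generate and write the five quarterly files plus ground_truth.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables, truth = generate(config)
    for name, table in tables.items():
        write_table(table, directory / table_filename(name, config.quarter_tag))
    truth.to_frame().to_csv(directory / "ground_truth.csv", index=False)
    return truth
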