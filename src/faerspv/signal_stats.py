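"""Reporting odds ratio (ROR) disproportionality analysis.

For a drug (or ATC class) *D* and an adverse event *E*, the deduplicated
database is cross-classified into the 2×2 table

    ==============  =========  ===========
                    event E    no event E
    --------------  ---------  -----------
    drug D          a          b
    other drugs     c          d
    ==============  =========  ===========

with the whole database as background.  The ROR is the sample odds ratio

    ROR = (a/b) / (c/d) = (a·d) / (b·c)

with the standard log-scale Wald interval

    95% CI = exp( ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d) ).

A positive signal requires the CI lower bound to exceed 1 AND at least
three target-event reports for the entity (a ≥ 3).  Zero cells leave the
ROR undefined (no continuity correction: the a ≥ 3 criterion cannot act
on such estimates anyway) and the signal flag false.

The module exposes both the statsmodels-style
:class:`DisproportionalityModel` / :class:`SignalResults` pair and thin
functional equivalents (:func:`build_contingency`, :func:`ror_signal`,
:func:`class_signal`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .drug_catalog import AtcMap, DrugRecord, map_atc2

__all__ = [
    "Z_95",
    "ContingencyTable",
    "SignalResult",
    "build_contingency",
    "ror_signal",
    "class_signal",
    "class_target_ids",
    "DisproportionalityModel",
    "SignalResults",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile
MIN_CASE_REPORTS = 3      # minimum a for a reportable signal


@dataclass(frozen=True)
class ContingencyTable:
    """Drug-event 2×2 report counts against the whole-database background."""

    a: int  # drug & event
    b: int  # drug, no event
    c: int  # event, no drug
    d: int  # neither

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalResult:
    """ROR point estimate, 95% CI and signal flag for one entity."""

    entity: str
    n_reports: int
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    is_signal: bool
    table: ContingencyTable | None = None


def build_contingency(
    target_report_ids: set, case_ids: set, all_report_ids: set
) -> ContingencyTable:
    """Cross-classify deduplicated reports by drug exposure and event status."""
    if not target_report_ids <= all_report_ids:
        raise ValueError("target reports not a subset of the database")
    if not case_ids <= all_report_ids:
        raise ValueError("case reports not a subset of the database")
    a = len(target_report_ids & case_ids)
    b = len(target_report_ids) - a
    c = len(case_ids) - a
    d = len(all_report_ids) - len(target_report_ids) - c
    return ContingencyTable(a, b, c, d)


def ror_signal(table: ContingencyTable, entity: str = "") -> SignalResult:
    """ROR with log-scale Wald 95% CI and the lower-bound>1 & a≥3 signal rule."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return SignalResult(entity, a, None, None, None, False, table)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    ci_low = math.exp(log_ror - Z_95 * se)
    ci_high = math.exp(log_ror + Z_95 * se)
    is_signal = ci_low > 1.0 and a >= MIN_CASE_REPORTS
    return SignalResult(entity, a, ror, ci_low, ci_high, is_signal, table)


def class_target_ids(
    class_code: str, atc_map: AtcMap, ps_drug_records: Iterable[DrugRecord]
) -> set[str]:
    """Reports with ≥1 primary-suspect ingredient in the ATC class (each once)."""
    out: set[str] = set()
    for r in ps_drug_records:
        ing = r.ingredient if r.ingredient else r.verbatim_name
        if class_code.upper() in map_atc2(ing, atc_map):
            out.add(r.primaryid)
    return out


def class_signal(
    class_code: str,
    atc_map: AtcMap,
    ps_drug_records: Iterable[DrugRecord],
    case_ids: set,
    all_report_ids: set,
) -> SignalResult:
    """Drug-class ROR: the target set pools all reports of the class's drugs."""
    target = class_target_ids(class_code, atc_map, ps_drug_records)
    table = build_contingency(target, case_ids, all_report_ids)
    return ror_signal(table, entity=class_code.upper())


class DisproportionalityModel:
    """ROR disproportionality of many entities against one case cohort.

    Parameters
    ----------
    case_ids : set
        Deduplicated primaryids of the target-condition cohort.
    all_report_ids : set
        Every deduplicated primaryid in the database (the background).
    target_sets : mapping of entity name -> set of primaryids
        Reports exposed to each entity (drug or pooled ATC class).
    """

    def __init__(
        self,
        case_ids: set,
        all_report_ids: set,
        target_sets: Mapping[str, set],
    ):
        self.case_ids = set(case_ids)
        self.all_report_ids = set(all_report_ids)
        self.target_sets = dict(target_sets)

    @classmethod
    def from_drug_records(
        cls,
        ps_records: Sequence[DrugRecord],
        case_ids: set,
        all_report_ids: set,
        entities: Sequence[str] | None = None,
    ) -> "DisproportionalityModel":
        """Build drug-level targets from primary-suspect records."""
        targets: dict[str, set] = {}
        for r in ps_records:
            ing = r.ingredient if r.ingredient else r.verbatim_name
            targets.setdefault(ing, set()).add(r.primaryid)
        if entities is not None:
            targets = {e: targets.get(e, set()) for e in entities}
        return cls(case_ids, all_report_ids, targets)

    @classmethod
    def from_atc_classes(
        cls,
        ps_records: Sequence[DrugRecord],
        atc_map: AtcMap,
        case_ids: set,
        all_report_ids: set,
        classes: Sequence[str] | None = None,
    ) -> "DisproportionalityModel":
        if classes is None:
            classes = sorted(atc_map.classes())
        targets = {
            code: class_target_ids(code, atc_map, ps_records) for code in classes
        }
        return cls(case_ids, all_report_ids, targets)

    def fit(self) -> "SignalResults":
        results = []
        for entity in sorted(self.target_sets):
            table = build_contingency(
                self.target_sets[entity], self.case_ids, self.all_report_ids
            )
            results.append(ror_signal(table, entity))
        return SignalResults(self, results)


class SignalResults:
    """Fitted disproportionality results; one row per entity."""

    def __init__(self, model: DisproportionalityModel, results: list[SignalResult]):
        self.model = model
        self.results = results

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, entity: str) -> SignalResult:
        for r in self.results:
            if r.entity == entity:
                return r
        raise KeyError(entity)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            t = r.table
            rows.append(
                {
                    "entity": r.entity,
                    "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                    "ror": r.ror,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "is_signal": r.is_signal,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["entity", "a", "b", "c", "d", "ror", "ci_low", "ci_high",
                     "is_signal"],
        ).sort_values("entity", ignore_index=True)

    def summary(self) -> str:
        df = self.to_frame()
        n_sig = int(df["is_signal"].sum())
        lines = [
            "ROR disproportionality analysis",
            f"database size N = {len(self.model.all_report_ids)}, "
            f"case cohort = {len(self.model.case_ids)}, "
            f"entities = {len(df)}, signals = {n_sig}",
            "",
        ]
        with pd.option_context("display.float_format", "{:0.2f}".format):
            lines.append(
                df.to_string(index=False, na_rep="--")
            )
        return "\n".join(lines)
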