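"""End-to-end orchestration: load → curate → find cases → signals → TTO → demographics.

The same workflow runs twice per analysis — once with the broad
heart-failure case definition and once with the three-PT acute
heart-failure definition — sharing the curated database and the
primary-suspect drug catalog.  Every stage writes its counts into a run
manifest so report conservation can be audited (nothing is silently
lost), and all CSV outputs are deterministically sorted so identical
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .faers_io import CurationLog, load_quarter
from .curation import (
    deduplicate,
    drop_invalid,
    filter_details,
    reports_from_demo,
)
from .case_finder import (
    CaseDefinition,
    builtin_ahf_definition,
    find_case_ids,
    load_case_definition,
    reactions_from_table,
)
from .drug_catalog import (
    AtcMap,
    NameMap,
    bundled_atc_map,
    bundled_name_map,
    drug_records_from_table,
    map_atc2,
    normalize_names,
    rank_top_drugs,
    select_primary_suspect,
)
from .signal_stats import DisproportionalityModel
from .onset_weibull import (
    WeibullTTOModel,
    compute_tto,
    median_iqr,
    therapy_from_table,
    DEFAULT_MIN_N,
)
from .demographics import outcomes_from_table, summarize

__all__ = ["RunConfig", "PipelineState", "run_full", "load_config"]

_BUNDLED_HF_PTS = Path(__file__).parent / "data" / "hf_pt_list.txt"


@dataclass
class RunConfig:
    """Validated run parameters (usually read from a YAML file)."""

    input_dir: Path
    quarter_tag: str
    output_dir: Path
    hf_definition: Path | None = None     # None -> bundled illustrative list
    name_map: Path | None = None          # None -> bundled map
    atc_map: Path | None = None
    top_n: int = 50
    min_tto_n: int = DEFAULT_MIN_N
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not self.input_dir.is_dir():
            raise FileNotFoundError(f"input directory {self.input_dir} not found")
        for attr in ("hf_definition", "name_map", "atc_map"):
            p = getattr(self, attr)
            if p is not None:
                p = Path(p)
                setattr(self, attr, p)
                if not p.exists():
                    raise FileNotFoundError(f"{attr} file {p} not found")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


@dataclass
class PipelineState:
    """Curated in-memory database shared by all analysis stages."""

    config: RunConfig
    log: CurationLog
    reports: list
    tables: dict
    stats_rows: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    @property
    def all_report_ids(self) -> set[str]:
        return {r.primaryid for r in self.reports}


def ingest(config: RunConfig) -> PipelineState:
    """Load the quarter, screen invalid reports, deduplicate case versions."""
    log = CurationLog()
    tables = load_quarter(config.input_dir, config.quarter_tag, log)
    reports = reports_from_demo(tables["DEMO"])
    reports, stats1 = drop_invalid(reports, log)
    reports, stats2 = deduplicate(reports, log)
    stats = stats1.merge(stats2)
    stats.check()
    surviving = {r.primaryid for r in reports}
    tables = {
        name: (filter_details(t, surviving) if name != "DEMO" else t)
        for name, t in tables.items()
    }
    state = PipelineState(config, log, reports, tables)
    state.stats_rows = stats.to_rows()
    state.counts.update(
        n_raw_reports=stats.n_input,
        n_dropped_incomplete=stats.n_dropped_incomplete,
        n_dropped_incorrect=stats.n_dropped_incorrect,
        n_dropped_duplicate=stats.n_dropped_duplicate,
        n_deduplicated=stats.n_output,
    )
    return state


def _case_definitions(config: RunConfig) -> dict[str, CaseDefinition]:
    hf_path = config.hf_definition or _BUNDLED_HF_PTS
    return {
        "hf": load_case_definition(hf_path, "heart failure"),
        "ahf": builtin_ahf_definition(),
    }


def _write_signals(df: pd.DataFrame, path: Path) -> None:
    df.sort_values("entity", ignore_index=True).to_csv(
        path, index=False, float_format="%.6g"
    )


def run_full(config: RunConfig) -> dict:
    """Execute the whole workflow; returns the manifest (also written to disk).

    Any stage failure propagates after the manifest-so-far and partial
    outputs are flushed, so a crashed run is still auditable.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stage_counts": {}, "outputs": []}
    manifest["config"] = {
        k: str(v) if isinstance(v, Path) else v
        for k, v in vars(config).items()
    }

    def flush(state: PipelineState | None = None):
        if state is not None:
            manifest["stage_counts"].update(state.counts)
            state.log.write(out / "run.log")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")

    state = None
    try:
        state = ingest(config)
        pd.DataFrame(state.stats_rows).to_csv(out / "curation_stats.csv",
                                              index=False)
        manifest["outputs"].append("curation_stats.csv")

        name_map = NameMap.load(config.name_map) if config.name_map else bundled_name_map()
        atc_map = AtcMap.load(config.atc_map) if config.atc_map else bundled_atc_map()
        reactions = reactions_from_table(state.tables["REAC"])
        ps_records = normalize_names(
            select_primary_suspect(drug_records_from_table(state.tables["DRUG"])),
            name_map, state.log,
        )
        therapy = therapy_from_table(state.tables["THER"])
        outcome_records = outcomes_from_table(state.tables["OUTC"])
        ps_seqs = {(r.primaryid, r.drug_seq) for r in ps_records}
        all_ids = state.all_report_ids
        state.counts["n_ps_drug_records"] = len(ps_records)

        for label, definition in _case_definitions(config).items():
            case_ids = find_case_ids(reactions, definition)
            state.counts[f"n_cases_{label}"] = len(case_ids)

            top = rank_top_drugs(ps_records, case_ids, config.top_n)
            pd.DataFrame(top, columns=["ingredient", "report_count"]).to_csv(
                out / f"top_drugs_{label}.csv", index=False
            )
            manifest["outputs"].append(f"top_drugs_{label}.csv")

            top_ings = [ing for ing, _ in top]
            drug_model = DisproportionalityModel.from_drug_records(
                ps_records, case_ids, all_ids, entities=top_ings
            )
            _write_signals(drug_model.fit().to_frame(),
                           out / f"drug_signals_{label}.csv")
            manifest["outputs"].append(f"drug_signals_{label}.csv")

            classes = sorted(
                {c for ing in top_ings for c in map_atc2(ing, atc_map, state.log)}
            )
            class_model = DisproportionalityModel.from_atc_classes(
                ps_records, atc_map, case_ids, all_ids, classes=classes
            )
            _write_signals(class_model.fit().to_frame(),
                           out / f"class_signals_{label}.csv")
            manifest["outputs"].append(f"class_signals_{label}.csv")

            sample = compute_tto(therapy, state.reports, case_ids,
                                 suspect_seqs=ps_seqs)
            state.counts[f"n_tto_usable_{label}"] = sample.n_usable
            row = {
                "cohort": label,
                "case_reports": sample.n_source_reports,
                "tto_usable": sample.n_usable,
                "median_days": None, "q25_days": None, "q75_days": None,
                "alpha": None, "alpha_ci_low": None, "alpha_ci_high": None,
                "beta": None, "beta_ci_low": None, "beta_ci_high": None,
                "profile": None,
            }
            if sample.n_usable >= 1:
                summary = median_iqr(sample)
                row.update(median_days=summary.median, q25_days=summary.q25,
                           q75_days=summary.q75)
            if sample.n_usable >= config.min_tto_n:
                res = WeibullTTOModel(sample, min_n=config.min_tto_n).fit()
                row.update(
                    alpha=round(res.alpha, 4),
                    alpha_ci_low=round(res.alpha_ci[0], 4),
                    alpha_ci_high=round(res.alpha_ci[1], 4),
                    beta=round(res.beta, 4),
                    beta_ci_low=round(res.beta_ci[0], 4),
                    beta_ci_high=round(res.beta_ci[1], 4),
                    profile=res.profile,
                )
            pd.DataFrame([row]).to_csv(out / f"tto_{label}.csv", index=False)
            manifest["outputs"].append(f"tto_{label}.csv")

            if case_ids:
                summary = summarize(state.reports, outcome_records, case_ids)
                df = summary.to_frame()
                df.to_csv(out / f"demographics_{label}.csv", index=False)
                manifest["outputs"].append(f"demographics_{label}.csv")

        manifest["outputs"] = sorted(set(manifest["outputs"]))
        flush(state)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        flush(state)
        raise
    return manifest
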