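# faerspv

Pharmacovigilance signal detection for drug-induced heart failure from
FAERS-style spontaneous adverse-event reports.

Spontaneous-report databases such as the FDA Adverse Event Reporting
System (FAERS) publish quarterly multi-table ASCII extracts: DEMO
(patient/administrative data), DRUG (medications with role codes), REAC
(MedDRA preferred terms, PTs), THER (therapy dates) and OUTC (outcomes),
linked by report version (PRIMARYID) and clinical case (CASEID).
`faerspv` turns such extracts into reproducible signal-detection
analyses for heart failure (HF) and acute heart failure (AHF), for
pharmacoepidemiologists, clinical pharmacists and drug-safety teams who
want the whole chain — curation, case finding, disproportionality,
onset profiling — as tested, scriptable code rather than spreadsheet
steps.

## What it computes

**Curation.** Reports missing identifiers or carrying unparseable
receipt dates (or impossible ages/weights) are dropped and counted; one
version per case survives deduplication — the most recent FDA receipt
date (FDA_DT), ties broken by the larger PRIMARYID.

**Case finding.** A cohort is the set of reports carrying at least one
PT from a narrow-scope, SMQ-style PT list (exact match after
normalisation; MedDRA codes take precedence when present). The
three-PT AHF definition (acute left/right ventricular failure, cardiac
failure acute; MedDRA codes 10063081, 10063082, 10007556) is built in.

**Disproportionality.** For each drug (primary-suspect records, names
normalised to ingredients) and each ATC level-2 class, the 2×2 table
`a, b, c, d` of report counts against the whole deduplicated database
gives the reporting odds ratio

```
ROR = (a·d)/(b·c),   95% CI = exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) )
```

with a positive signal when the CI lower bound exceeds 1 and `a ≥ 3`.

**Time to onset.** Days from the earliest suspect-drug start date to
the event date are summarised by median and quartiles and fitted with a
two-parameter Weibull distribution by maximum likelihood. The shape
parameter β and its 95% CI classify the hazard: CI < 1 → *early
failure* (risk concentrated after initiation), CI ∋ 1 → *random
failure*, CI > 1 → *wear-out failure*.

**Demographics.** Table-1-style summaries (sex, age and weight bands,
reporter occupation, countries, seriousness outcomes) with half-up
rounded percentages, plus derived ratios (male/female ratio, share of
patients ≥65 among known ages).

**Synthetic data.** `faerspv.synthetic_faers` generates five-table
quarters with planted drug-event odds multipliers, Weibull onset
intervals, duplicate case versions and realistic marginals, so the full
pipeline is testable without FAERS access.

## Worked example

```python
from faerspv import SimConfig, RunConfig, run_full
from faerspv.synthetic_faers import write_quarter

write_quarter(SimConfig(n_cases=50_000, seed=42), "demo/q")
manifest = run_full(RunConfig(input_dir="demo/q", quarter_tag="23Q4",
                              output_dir="demo/out"))
print(manifest["stage_counts"])
```

```
{'n_raw_reports': 55032, 'n_dropped_incomplete': 0, 'n_dropped_incorrect': 0,
 'n_dropped_duplicate': 5032, 'n_deduplicated': 50000, 'n_ps_drug_records': 50000,
 'n_cases_hf': 772, 'n_tto_usable_hf': 559, 'n_cases_ahf': 77, 'n_tto_usable_ahf': 58}
```

55,032 raw report versions reduce to 50,000 unique cases (the generator
planted 10% duplicate versions); 772 reports carry an HF term. The
drug-level signal table (`demo/out/drug_signals_hf.csv`):

```
       entity   a     b   c     d       ror   ci_low   ci_high  is_signal
   amlodipine 151 14962 621 34266  0.556877 0.465668  0.665950      False
 atorvastatin  94  9789 678 39439  0.558580 0.449687  0.693842      False
    ibuprofen 184 14839 588 34389  0.725196 0.613859  0.856727      False
    metformin  77  7407 695 41821  0.625544 0.493697  0.792603      False
rosiglitazone 266  2231 506 46997 11.073900 9.489640 12.922700       True
```

The generator planted an odds multiplier of 12.51 on rosiglitazone and
1.0 on everything else: the fitted ROR 11.07 (95% CI 9.49–12.92) flags
exactly that drug. And the pooled onset fit (`demo/out/tto_hf.csv`)
recovers the planted Weibull(α=191, β=0.49) early-failure kinetics:
median 100 days (IQR 16–393), β̂ = 0.49 (95% CI 0.46–0.52), profile
*early failure*.

The same run from a shell:

```
faerspv simulate --out-dir demo/q --seed 42 --n-cases 50000
faerspv run-all --input-dir demo/q --quarter-tag 23Q4 --output-dir demo/out
```

For real extracts, point `--input-dir` at a directory holding
`DEMOyyQq.txt` etc., and supply your own licensed PT list
(`--hf-definition`), name map and ATC map; the bundled maps cover the
ingredients used in the examples and are plain editable text.

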