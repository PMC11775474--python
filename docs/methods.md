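# Methods

## Data model and curation

A FAERS-style quarter is five dollar-delimited ASCII tables with one
header line and no quoting. Rows whose field count disagrees with the
header (e.g. a stray `$` in free text) are unrecoverable in this
dialect and are dropped and counted rather than repaired; the curation
log records `rows_in = rows_kept + rows_dropped` per file. Blank
fields, `NULL` and similar tokens collapse to a single missing marker.

Dates arrive at year, month or day precision (4/6/8 digits). They are
kept as partial dates and ordered by the zero-padded digit string —
a deterministic total order that never imputes missing components, so a
month-precision receipt date compares correctly against full dates.

*Incomplete* reports (missing PRIMARYID or CASEID) and *incorrect*
reports (unparseable/absent FDA_DT, or age ≥ 150 years / weight ≥
700 kg after unit conversion) are removed before deduplication. These
operationalisations are this package's own: the terms are standard in
FAERS curation but have no canonical definition, so the minimal
checkable reading was chosen and is enforced by type invariants. Age
unit codes convert with calendar-free divisors (1 DEC = 10 y, 12
months, 52 weeks, 365.25 days, 8766 hours per year); weights accept KG,
LBS (×0.45359237) and GMS.

Deduplication keeps, per CASEID, the version with the latest FDA_DT,
breaking ties by the numerically larger PRIMARYID (lexicographic
fallback for non-numeric ids keeps the order total). Detail rows of
discarded versions are discarded with them. The operation is
idempotent and preserves first-appearance order, which is what makes
whole-pipeline reruns byte-identical.

## Case definitions

A case definition is a flat set of normalised PT strings with optional
MedDRA codes — the narrow-scope SMQ style, where specificity is the
point. Matching is exact after trimming/case-folding; when both the
reaction and the definition carry numeric codes, the code comparison is
authoritative. No substring or fuzzy matching is offered: fuzziness
would trade the specificity a narrow-scope search exists for against
uncontrolled sensitivity. The three-PT AHF definition is built in; the
bundled HF PT list is an illustrative synthetic stand-in (MedDRA is
licensed), so analyses of real extracts should supply their own list —
absolute case counts depend directly on it.

## Drug catalog

Only primary-suspect (role `PS`) drug records enter signal detection.
Verbatim names fold onto ingredients through a plain-text map; unmapped
names pass through as themselves (losing a drug because it is absent
from the map would silently bias rankings), and names mapped to the
reserved `EXCLUDE` token are dropped and counted. Combination products
are their own catalog entities rather than being split into components,
matching how fixed-dose combinations are listed in practice. Ranking
counts distinct (ingredient, report) pairs, ties broken alphabetically
for run-to-run determinism. ATC level-2 classes come from a second
editable two-column file; one ingredient may map to several classes.

## Disproportionality

For entity *D* (drug or pooled ATC class) and cohort *E*, the 2×2 table
is built from report-id sets against the **entire deduplicated
database** as background, counting distinct reports — a report with two
same-class suspect drugs contributes once. The reporting odds ratio
`(a·d)/(b·c)` carries the log-scale Wald interval
`exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`; a signal requires CI lower
bound > 1 and `a ≥ 3`. Zero cells yield an explicitly undefined ROR
and a false signal flag, with no Haldane 0.5 continuity correction: the
`a ≥ 3` rule cannot act on such estimates, and a corrected point value
would suggest precision the data lack. No multiple-testing adjustment
is applied; the output carries raw CIs per entity.

One behaviour worth knowing when reading output on data with a strong
true signal: background drugs can show ROR < 1 even when generated at
odds multiplier 1, because the signal drug's cases inflate the
event rate of the "all other drugs" comparator. This masking is a
well-known property of disproportionality statistics, not a defect of
the estimator.

## Time to onset and the Weibull shape parameter test

TTO is `event_dt − earliest start_dt` over the report's suspect-drug
therapy rows, in days. Month-precision dates impute day 1 on **both**
sides (symmetric imputation avoids directional bias); year-precision
dates are unusable and excluded; `tto ≤ 0` is excluded because the
Weibull log-likelihood is undefined at 0 for β < 1. All exclusions are
counted by reason. Median and quartiles use linear interpolation and
half-up rounding to whole days.

The two-parameter Weibull is fitted by maximising the likelihood in
`(ln α, ln β)` with analytic gradients (L-BFGS, tolerance 1e-8 on the
objective), started from the log-moment estimator
`β₀ = π/(√6·sd(ln t))`, `ln α₀ = mean(ln t) + γ/β₀` — a start that is
already consistent and keeps the optimiser robust for the heavy-tailed
β < 1 regime typical of onset data. 95% CIs are Wald intervals on the
log-parameter scale from the numerically differenced observed
information, exponentiated back; at the sample sizes where the test is
used (hundreds to tens of thousands) these agree with profile
likelihood to well past the two decimals reported. The default floor
of 30 usable values reflects where the Wald approximation becomes
defensible; below it the fit raises rather than returning fragile
intervals. Fits are pooled per cohort (HF, AHF), not per drug.

The profile rule is exhaustive over valid CIs: upper bound < 1 → early
failure; lower bound > 1 → wear-out failure; otherwise random failure.

## Demographics

Sex, age band, weight band and occupation are true partitions (counts
sum to the cohort total); countries report the top-k plus "Others";
outcomes are multi-label, each report contributing once per distinct
outcome band, so their percentages may sum past 100%. The
exactly-100 kg boundary uses the half-open convention `[50, 100)` /
`[100, ∞)`. Percentages round half-up to one decimal; the derived
male/female ratio and the ≥65 share round half-up to two. The ≥65
share uses known-age reports as denominator — the only denominator
under which the published figure it mirrors is arithmetically
consistent. Half-up (not banker's) rounding matches how such tables
are printed.

The bundled `published_table1_counts.csv` carries the printed per-band
counts of a published FAERS heart-failure cohort, used as *input* for
recomputing percentages and ratios; one printed percentage (outcome
"Unknown", 7,236/216,362) recomputes to 3.3 rather than the printed
3.4, and the recomputed value is the one asserted.

## Synthetic data generator

The generator emulates what the pipeline must be able to recover, with
defaults chosen as the emulated study conditions:

* **Planted odds.** Each case gets one primary-suspect drug by market
  share; the target event fires with probability
  `p₁ = r·p₀/(1−p₀+r·p₀)`, so the drug's population reporting odds
  ratio is exactly its multiplier `r`. Default background event
  probability `p₀ = 0.01` (spontaneous-report cohorts are rare-event);
  default drugs: one diabetes-class drug at `r = 12.51` — the magnitude
  of a strong class-level signal — against four background drugs at
  `r = 1`.
* **Onset kinetics.** TTO is drawn per drug from Weibull(α, β),
  default (191.02, 0.49): day-scale early-failure kinetics. Dates are
  derived backwards from a fixed anchor so every emitted date parses;
  5% of dates are degraded to month precision and 15% of start/event
  dates are blanked, exercising the imputation and exclusion paths
  (real onset completeness is far lower, but lower rates would starve
  small test runs of usable values).
* **Duplicates.** With probability 0.1 a case is emitted as two
  versions differing only in PRIMARYID and FDA_DT (10% of duplicates
  share the FDA_DT to exercise the tie rule) — exactly the fields the
  dedup rule keys on, and nothing else, so the test isolates the rule.
* **Marginals.** Sex/age/weight/occupation/country/outcome are drawn
  from distributions shaped like a published HF cohort table; 30% of
  reports carry a concomitant (role C) drug and 30% of suspect names
  are emitted as brand names to exercise normalisation.

What the generator does **not** emulate: misspelled free-text drug
names, multi-quarter case evolution, correlated demographics,
indication confounding, reporting-volume trends, or censoring. Passing
tests therefore demonstrate that the machinery recovers planted truths
under clean FAERS-shaped data, not that real-FAERS estimates are
unbiased — reporting bias, duplicates across CASEIDs and name chaos in
real data are out of scope by design.

## Problem sizes and numerical choices

The test suite runs planted-signal recovery at 2×10⁵ cases (sampling
error of the ROR ≈ 4% at that size, comfortably inside the ±15%
recovery band), null calibration at 100 seeds × 10⁴ cases, and Weibull
recovery at the published sample sizes (62,186 and 2,277). Property
tests use fixed-seed or derandomised generators throughout; every CSV
output is deterministically sorted, so identical inputs give
byte-identical outputs.

## Known limitations

* ROR is the only estimator (no PRR/BCPNN/EBGM) and there is no
  stratification or adjustment; signals are disproportionalities, not
  causal effects.
* Exact-match case finding cannot absorb PT misspellings; garbage PTs
  simply never match.
* The Weibull fit ignores censoring — reports without onset data are
  excluded, not censored — so β̂ describes the reported-onset
  subsample.
* The bundled name and ATC maps cover the drugs used in examples and
  tests; real analyses need fuller, licensed vocabularies.
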