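# Methods

## Model and estimand

The analysis unit is the deduplicated spontaneous report.  For a drug–event
pair, reports are cross-classified into a 2×2 table: a (drug as primary
suspect, event PT present), b (drug, no event), c (no drug, event), d
(neither).  The reporting odds ratio ROR = (a·d)/(b·c) estimates how many
times higher the odds of the target event (versus any other reported event)
are among the drug's reports than among all other reports.  Uncertainty is
quantified with the Woolf (log-normal) interval,
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)) with z = 1.96, and a signal is declared
when the lower bound strictly exceeds 1.0.  The ROR is a reporting-level
measure on a voluntary database: it assumes nothing about incidence and is a
hypothesis-generating statistic, not a causal effect.

The Woolf interval with z = 1.96 exactly was adopted because it reproduces,
to the printed two decimals, every published confidence interval whose 2×2
table can be reconstructed from in-text numbers (see `pvror.reference` and
the closure tests); z is configurable.

## Pipeline conventions

* **Parsing.** Text fields are trimmed and upper-cased before any
  comparison; FAERS capitalization is inconsistent.  Dates parse only as
  8-digit YYYYMMDD — partial dates become missing, keeping dedup keys
  deterministic.  Ages are (value, unit-code) pairs compared verbatim with
  no unit conversion; a conversion rule would add assumptions the matching
  step does not need.
* **Deduplication.** Stage 1 keeps one report per case number; stage 2
  collapses reports agreeing exactly on age, sex, event date and reporter
  country.  "Most recent" is made total by the key (case_version,
  receipt_date, primary_id), so survivors are deterministic.  Stage 2
  requires all four fields present: grouping on missing values would merge
  unrelated reports, so missingness opts a report out of grouping.  The
  four-field rule is applied literally, without additionally requiring
  matching drug or reaction content; with content matching the second stage
  would be strictly more conservative.
* **Exposure.** Name matching is exact after normalization (upper-case,
  whitespace collapse, and stripping of trailing dosage/form tokens — the
  stop-list TABLET/CAPSULE/INJECTION/MG/ML/% plus bare numbers and fused
  number+unit tokens such as `500MG`, which otherwise survive the stop-list
  pass).  No fuzzy matching: silent false merges would corrupt counts.
  Combination products (e.g. piperacillin-tazobactam) are single generics.
  The verbatim name is tried before the active-ingredient field.  Drugs with
  fewer than three PS reports overall are excluded; the threshold applies to
  total PS reports, not event-specific counts.
* **Case definitions.** Exact PT-set intersection against flat term lists.
  The AKI definition is the union of a user-supplied acute-renal-failure SMQ
  list and the literal PT "Renal failure acute".  SMQ scope (narrow/broad)
  is whatever the supplied file contains; the shipped hepatic and renal
  lists are synthetic stand-ins (MedDRA content is licensed) intended for
  tests and examples only.
* **Variants.** Adjusted RORs remove every report listing any of the seven
  statins in any role code — concomitant statins are the confounder of
  interest, so the filter is not limited to suspect rows.  Subgroup tables
  stratify exposure by condition status with all other reports (including
  the drug's other stratum) as comparator; this is the only comparator
  consistent with the published subgroup intervals given the published
  stratum counts.  The date-range filter applies to the receipt
  (submission) date; reports with a missing receipt date are excluded and
  counted in the run log.
* **Zero cells.** The default leaves the estimate undefined with a reason
  code (`zero_cell:<cells>`); the Haldane–Anscombe +0.5 correction is
  available by flag.  Display rounding is two decimals, half-up.

## Table reconstruction (`solve_b`)

Published disproportionality tables often print a, the point estimate, and
the database totals but not b.  From ROR = a·(N−a−b−c)/(b·c), b =
a·(N−a−c)/(c·ROR + a), rounded to the nearest integer.  Recomputing the
point estimate and CI on the reconstructed table and comparing with the
printed values closes the loop on both the reconstruction and the CI
implementation.

## Synthetic generator

`pvror.synthetic` emulates the statistical structure the estimator assumes
rather than real FAERS marginals.  Each unique case draws one PS drug
(catalog drugs by their marginal exposure probabilities, the remainder a
decoy background drug), then an event indicator with odds
base_odds × true_ror(drug) × statin_event_boost^statin.  Event generation is
odds-multiplicative so the planted parameter is exactly the report-level
quantity the ROR estimates.  Reactions are the event PT plus Poisson(λ=2)
decoy PTs; conditions plant one PT from the hepatic/AKI term fixtures.

Defaults (chosen once as plausible for a validation generator, not fitted to
any dataset): event base rate 0.05 among unexposed reports — high relative
to rhabdomyolysis's ~0.33% share of real FAERS reports, but necessary for
informative 2×2 tables at the thousands-of-cases scale the tests use;
duplicate_version_rate 0.2 and profile_duplicate_rate 0.1 so both dedup
stages are exercised; statin co-reporting 0.3 given catalog-drug exposure
versus 0.05 background with a 10× event-odds boost, qualitatively matching
statins' strong association with rhabdomyolysis; per-field missingness
0.05–0.2; condition rates 0.05.

Two constructions keep ground truth exact rather than approximate:
demographic 4-tuples are rejection-sampled to be unique across distinct
cases, so planted profile duplicates are the only stage-2 matches; and
profile duplicates clone the four fields and all content verbatim, so
stage-2 dedup is exercised deterministically and the analyzed set equals the
manifest's unique cases report-for-report.  Receipt dates are always
present.  All randomness flows from one seeded numpy generator; a fixed
(config, seed) yields byte-identical files.

What passing tests therefore show: the pipeline recovers planted truth
exactly under FAERS-like *structure* (duplicates, roles, synonym noise,
decoy terms).  What they do not show: robustness to real-world messiness the
generator omits — misspelled drug names beyond the synonym list, age-unit
heterogeneity, country aliases, partially overlapping duplicates, reporting
waves — nor, of course, anything causal.

## Simulation studies

Frequentist checks sample from the generator's case-level core
(`sample_population`, the same routine `generate()` uses) without writing
files: 2,000 datasets of 2,000 cases with a planted true ROR of 3 give Woolf
interval coverage within 95% ± 2%; and with planted statin confounding a
null antibiotic's crude ROR exceeds its statin-adjusted ROR in essentially
every run (sign test over 200 datasets), reproducing the rationale for the
adjusted analysis.  Simulation seeds are fixed in the tests.

## Numerical and degenerate-input choices

* Recency ties beyond case_version fall through to receipt_date, then to the
  lexicographically greatest primary_id — arbitrary but total.
* `solve_b` refuses inputs with no positive solution (b < 1 or d < 1).
* Empty input files parse to empty sequences with a warning; an empty term
  list is a hard error (an empty case definition matches nothing and is
  almost certainly a user error).
* Reports with no drug rows are dropped before analysis and counted in the
  run log; they can hold no exposure and would only inflate d.
* A verbatim name shared by two generics' synonym sets is rejected when the
  dictionary is built, not silently resolved.

## Known limitations

Legacy (pre-2012Q4, ISR-keyed) files are supported only through a
user-supplied column map; no probabilistic record linkage; no MedDRA
hierarchy traversal or LLT→PT mapping; no PRR/IC/EBGM estimators and no
multiple-testing correction; the shipped drug dictionary is a small fixture
(the studied antibiotics and seven statins) — production use requires a
fuller dictionary file.
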