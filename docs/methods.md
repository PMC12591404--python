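# Methods

## Scope and data model

The package analyses individual case safety reports (ICSRs) in the shape a
FAERS quarterly extract provides: four flat tables (demographics, drugs,
reactions, outcomes) joined on `(case_id, version_id)`. The real FAERS
primaryid/caseid duality is collapsed to this single pair — the analysis
needs nothing more. Sex is normalised to M/F/OTHER/UNKNOWN (blank → UNKNOWN,
any non-M/F code → OTHER), countries and outcome codes keep an explicit
UNKNOWN level, and `interaction_attributed` is carried as an explicit
boolean column: real extracts encode "the reporter blamed a drug–drug
interaction" only implicitly, and a concrete column is the only testable
representation of that exclusion rule.

## Drug and event mapping

Drug classes are matched by case-insensitive, whitespace-normalised
substring search of the verbatim `drugname`/`prod_ai` strings against a
term dictionary (generic names, brands, formulation terms combined as OR).
Short, ambiguous terms (`gum`, `lozenge`, `inhaler`, `nasal spray`,
`thrive`) are flagged word-boundary-only so "GUMMY VITAMIN" is not
captured. Exclusion terms act per drug entry: a Wellbutrin entry
contributes nothing to the bupropion class (the brand is mostly prescribed
for depression), but another entry on the same report can still match NRT.
GI events are a flat, case-insensitive Preferred-Term list: primarily the
gastrointestinal SOC plus oral/digestive terms commonly co-reported with
cessation pharmacotherapy (dry mouth, hiccups, dental caries, decreased
appetite, anorexia). The shipped list is user-replaceable; no MedDRA
hierarchy traversal is attempted.

## Deduplication

Two stages, both deterministic:

1. group by case id, keep the highest `version_id`; ties broken by latest
   report date, then by the lexicographically greatest canonical
   serialization (the data provide no third-level rule, so the tie-break is
   simply documented and fixed);
2. collapse survivors sharing the full identifying key (case id, report
   date, sorted drug names, sorted indications, sex, country, age at
   integer-year precision; missing age matches missing age).

After stage 1 each case id is unique, so stage 2 is a safety net that
matters mainly when it is invoked on data that skipped stage 1; verbatim
exact duplicates are in practice removed inside stage 1's groups and
counted separately in the audit. Dedup is idempotent and never increases
the record count.

## Analysis set and counting conventions

The default role policy is primary-suspect-only (`PS_only`); a wider
`suspect_or_interacting` policy (PS/SS/I) is available because inclusion
criteria in the field are stated both ways and the two can legitimately
differ — the narrow set is always a subset of the wide one. Reports whose
GI event the reporter attributed to an interaction or concomitant
medication are removed from the analysis universe.

Counting is report-level throughout: `a` is the number of reports carrying
drug and event, never the number of event mentions, and a report naming
the event under both the target drug and another drug counts only in `a`.
The background (`c`, `d`) is every analysis-universe report not matching
the target class, *including* the other cessation drugs; a
`background_exclude` option removes fellow target classes for sensitivity
analysis. Reports with sex OTHER/UNKNOWN enter the ALL stratum but neither
sex stratum, so `a_M + a_F ≤ a_ALL` with equality iff no such report
carries the event.

Demographic summaries give n (%) per drug class on the class's own total;
countries individually under 1% of the class's reports fold into "Other
countries" (threshold evaluated per class); outcome codes are not mutually
exclusive, so that block may exceed 100%. Percentages are rounded to two
decimals. One published convention is deliberately not reproduced: the
source summary reports a female GI share for bupropion (4.22%) larger than
the drug's overall share (2.11%), which cannot arise from a within-drug
partition; this package uses the self-consistent within-drug denominator.

## Signal statistics

PRR and ROR are computed from the 2×2 cells with Woolf (log-normal) 95%
intervals at z = 1.96. The field names no CI method for these metrics, so
Woolf — the standard in the disproportionality literature — is used for
both. χ² is Pearson without Yates correction by default (a `--yates` flag
exposes the corrected variant; which variant underlies published "χ² ≥ 4"
thresholds is generally unstated, and the convention used is recorded in
the run manifest). Signal rules: PRR signal ⇔ DE ≥ 3 ∧ PRR ≥ 2 ∧ χ² ≥ 4;
ROR signal ⇔ DE ≥ 3 ∧ lower CI bound > 1.

Zero-cell handling differs by context, matching practice: in the overall
analysis a zero `a` cell is reported as an undefined-signal marker (NaN,
no signal — DE ≥ 3 excludes such pairs anyway); in the stratified analysis
the Haldane–Anscombe correction adds 0.5 to all four cells iff any cell is
zero, and the result is flagged `corrected`.

## Sex-heterogeneity screen

For each drug–event pair the male and female tables are tested for a
common odds ratio with the Breslow–Day χ². The common-OR under the null is
the Mantel–Haenszel estimator (not the conditional MLE) — the test's most
widespread implementation — with Tarone's adjustment off by default; both
are exposed. The expected `a` cell per stratum solves
`R(r1−E)(c1−E) = E(n−r1−c1+E)` in closed form, taking the root inside
`(max(0, r1+c1−n), min(r1, c1))` with tolerance 1e-10; an inadmissible
root is a hard error naming the stratum. p-values come from the upper χ²
tail with df = strata − 1; the unit tests cross-check statistic and
p-value against statsmodels' `StratifiedTable.test_equal_odds` and a
label-permutation null.

The screen applies a pre-specified stability filter — DE_male + DE_female
strictly greater than 20 — before calling a pair significant at two-sided
p < 0.05, with no multiplicity adjustment (the screen is explicitly
hypothesis-generating). Direction (F > M or M > F) compares the sex RORs
of significant pairs only.

## Synthetic cohort generator

Each report independently draws one suspect drug (three target classes
plus 20 generic background drugs), a sex, an age band, a country and an
interaction-attribution flag; each catalog event then occurs with
probability q where `odds(q) = odds(p0) · ψ(drug, event, sex)`. ψ is
specified on the odds scale so the ROR is the natural estimand; PRR
recovery is only asymptotic (rare-event regime). Events are conditionally
independent given drug and sex — disproportionality treats each pair
marginally, so dependence modelling would add nothing testable. Ages are
drawn as bands (<25, 25–40, 40–55, >55, boundary years 40 and 55 falling
in 40–55) and materialised as integer years inside the band. A report
whose event draw comes up empty receives the fallback PT "Drug
ineffective" so every report carries at least one event; this biases only
that PT's own margin, by at most the probability of an empty draw.

Defaults mirror the study conditions at desk scale: 100,000 reports; sex
margins F 0.616 / M 0.359 / OTHER 0.001 / UNKNOWN 0.024; a US-dominated
country mix with several sub-1% countries to exercise the aggregation
rule; age-band mix concentrated in 40–55; per-event background
probabilities between 0.001 and 0.05 (generator conventions — the real
database's background incidences are not published); and sex-specific ψ
values following the published sex-stratified GI pattern (e.g.
varenicline–nausea 5.10 M / 6.41 F, NRT–hiccups 42.7 M / 109.81 F,
NRT–nausea stronger in men). Outcome codes are drawn independently at
small rates (an extension beyond the minimal field list, needed so outcome
summaries are non-trivial). Duplicate versions (2%) and exact duplicates
(1%) are injected from a sub-seed derived from the master seed, so
toggling the rates never perturbs the base cohort. All randomness flows
from one integer seed; identical seeds give bit-identical cohorts.

What the generator does *not* emulate: reporting-delay dynamics,
stimulated reporting, drug–drug-interaction pharmacology, event-event
dependence, notoriety bias and drug-specific demographic profiles.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under a faithful idealisation of spontaneous
reporting — not the epidemiology of any real drug.

### Analytic oracle and fast simulation paths

`expected_table` evaluates the exact expected 2×2 cells from the
configuration (closed-form mixture over sexes and drug categories),
pre-duplicates. `simulate_stratified_counts` draws the sufficient
statistics of the generator directly (multinomial sex/drug splits,
binomial event counts) — the identical law at a fraction of the cost —
and powers the calibration studies in `pvsex.validation`:

- **size**: ψ = 2 in both sexes (homogeneous but non-null), 20,000 reports
  per replicate (≈57/38 expected co-reports per stratum); rejection rate
  at α = 0.05 should sit near 0.05;
- **power**: ψ = 4.0 (F) vs 1.5 (M), 60,000 reports with drug share 0.15
  (≈330/780 expected co-reports — comfortably in the regime the screen is
  meant for);
- **coverage**: pooled ψ = 3 at 50,000 reports via the full per-report
  frame draw; since the odds multiplier is equal in both sexes and the
  background rate is sex-independent, the pooled estimand equals ψ exactly
  and the Woolf 95% CI should cover it ~95% of the time.

Problem sizes were chosen once, by expected-count arithmetic, so the
χ² asymptotics are on safe ground while the studies stay desk-scale.

## Numerical and degeneracy choices

Identical strata give a Breslow–Day statistic of exactly 0 (p = 1) up to
floating-point residue below 1e-9. Degenerate tables (a zero margin)
yield χ² = 0; undefined PRR/ROR are NaN markers, never exceptions. The
stability filter is strict (a DE sum of exactly 20 fails). CSV artifacts
serialise floats at 4 decimals, flags as 0/1, and blank heat-map cells as
empty fields — never 0 or an NA string — keeping "no qualifying reports"
distinct from "PRR = 1".

## Known limitations

Published per-pair RORs/PRRs for the real database are not recomputable
here: they require the full background report counts, which are not
printed anywhere. The acceptance machinery therefore validates the
arithmetic on the published demographic counts exactly, and everything
else property-wise against oracles and the generator's known truth.
Disproportionality statistics measure reporting association, not risk or
causation; nothing in this package adjusts for under-reporting, notoriety
or channeling bias.
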