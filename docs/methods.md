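# Methods

## Data model and conventions

A spontaneous report carries: an opaque unique `report_id`; sex
(male/female/unknown); age in whole years (0–14 is the pediatric window used
throughout, `None` when unknown); one or more raw drug-name strings; one or
more raw ADR-term strings; the reporter's causality assessment on the
six-level scale certain / probable / possible / unlikely / unassessable /
unknown; severity (serious vs non-serious, per the usual regulatory
definition: death, life-threat, disability, organ damage, or (prolonged)
hospitalization); novelty (new vs known relative to the package insert);
outcome (recovered / improved / sequelae / death / unknown); and route
(injection / oral / other / unknown).

Tables are UTF-8 CSV with a header; multi-valued cells use `;`. Unparseable
enum values are coerced, never dropped: sex/causality/outcome/route fall to
their `unknown` member; severity and novelty have no unknown member in the
regulatory vocabulary, so unparseable values fall to `non_serious` / `known`
(the conservative SRS reading: a report not positively marked serious is
non-serious). Every coercion is counted in a parse log, so
`len(parse_log)` equals the number of coerced fields exactly.

Drug dictionaries map raw strings to canonical generic (API) names and must
be idempotent on canonicals; chained or cyclic mappings and conflicting
synonym rows are hard errors. ADR dictionaries map raw strings to preferred
terms, each with exactly one system-organ class (WHO-ART style).

## Preprocessing

Inclusion keeps reports with age inside the configured window (default 0–14),
causality in the allowed set (default certain/probable/possible), and — when a
drug-class filter is supplied — at least one suspected drug in the class.
Every exclusion carries a machine-readable reason code. Unknown-age reports
stay in the included set by default and are only omitted from age breakdowns
downstream; a policy flag can exclude them at the filter instead
(`age_unknown` reason). Filtering always partitions its input.

Event expansion forms one drug–event combination (DEC) per distinct
(report, drug, ADR) triple — the cartesian product of a report's drugs and
terms, deduplicated within the report. The same ADR under two suspected drugs
in one report yields two events, matching the per-drug counting unit of
disproportionality analysis. Output order is a stable sort by
(report_id, drug, adr), so expansion is order-independent.

## Descriptive statistics

Percentages and ratios are rounded half-up to two decimals (the precision of
conventional safety tables); internal arithmetic is exact decimal, so printed
values like 36.18% reproduce bit-for-bit from their counts. Report-level
tables use the report count as denominator, event-level tables the event
count; every `FrequencyTable` records its denominator explicitly because the
two scales differ (≈1.3 events per report). Cumulative percentages are
computed from cumulative counts, not by summing rounded row percentages.

Age strata default to single-year bins 0..14; the dichotomy 0–4 vs 5–14 used
for severity comparisons is a named preset. The Pearson chi-square is
hand-rolled (five lines) so the Yates convention matches the fourfold-table
statistic below — the correction subtracts 0.5 from |O−E| and clamps at zero,
and is applied only to 2×2 tables on request; p-values come from
`scipy.stats.chi2.sf`. Tests cross-check against
`scipy.stats.chi2_contingency` on random r×c tables; a zero margin raises
`degenerate margin` rather than returning 0/0.

## Disproportionality

Formulas as in the README. Numerical and policy choices:

* **Zero cells.** No continuity correction by default; a zero cell makes the
  log-scale SE incomputable, so the estimate is NaN and the flag false —
  "undefined" is a value state, not an exception. A Haldane–Anscombe +0.5
  option exists for exploration but does not participate in flagging
  defaults.
* **PRR interval.** Some printed sources show `ln(ROR)` inside the PRR
  interval's exponent; that is inconsistent with the PRR standard error, and
  the interval here is `exp(ln PRR ± 1.96·SE(ln PRR))`.
* **Yates denominator.** The standard `(a+b)(c+d)(a+c)(b+d)` is used. A
  nonstandard variant `(a+b)(a+c)(b+c)(c+d)` occasionally appears in print
  and is available behind `printed_denominator=True` for comparison only.
* **Yates clamp.** `(|ad−bc| − N/2)` is clamped at zero before squaring, so
  near-independent tables score 0 instead of an inflated statistic.
* **Background scope.** The supplied event set is the background; callers
  widen it by passing a larger universe. Mining scores every DEC with a ≥ 1
  (sub-threshold DECs can never flag but remain inspectable), orders results
  by (drug, descending ROR, adr), and computes consensus as the conjunction
  of the three per-method flags — so the consensus set is a subset of each
  method's set by construction, a property the tests verify empirically too.
* **Counting unit.** Events by default; `unit="reports"` counts distinct
  reports per cell instead.
* Display rounding is two decimals; all internal math is full precision.

Algebraic facts validated exhaustively on all tables with cells 1..12 and by
randomized tests: sign(ROR−1) = sign(PRR−1) = sign(ad−bc); PRR ≤ ROR whenever
ROR > 1 (since ROR/PRR = (ad+bd)/(bc+bd)); the Yates statistic is invariant
under swapping the table's rows; and all three statistics are monotone in `a`
(margins' complements held fixed) on the positive-association side ad ≥ bc —
below independence the corrected χ² first falls toward zero, so monotonicity
is only claimed and tested for ad ≥ bc.

## Synthetic SRS generator

Each synthetic report draws one suspected drug from catalog marginals, an ADR
count from a zero-truncated Poisson, and that many distinct ADR terms by
weighted sampling without replacement (Gumbel top-k, which reproduces
successive renormalized draws) from the drug's term distribution. An
*implant* (drug, adr, rate ratio ρ) multiplies that term's baseline
probability p within the drug's reports, after which the row renormalizes —
so the realized within-drug share is ρp/(1 + (ρ−1)p), slightly below ρp. This
attenuation is the exact expectation the generator tests check against; it
mirrors the relative-reporting-rate quantity the PRR estimates. Sex, age,
causality, novelty, severity, outcome, route and date are drawn independently
from configurable marginals; severity is independent of the DEC by default,
with an optional per-drug serious-probability override for stratified
severity patterns.

Defaults emulate a large published pediatric cephalosporin SRS extract:
37 drugs with marginals proportional to the published per-drug report counts;
22 ADR terms proportional to the published event counts with WHO-ART-style
organ classes; mean 1.3043 ADR terms per report (the published
events/reports ratio); 6.63% serious; sex split 9,740:6,103 with 14 per
15,857 unknown; ~0.04% unknown age; routes 96.30% injection / 3.66% oral;
outcomes consistent with 99.18% improved-or-recovered and a ~0.025% death
rate; ages skewed to 0–3 (the two published youngest-bin counts, remainder
uniform over 4–14, since only those two bins are printed numerically).
The zero-truncated Poisson is sampled by inverse CDF through the untruncated
quantile function, which is exact and remains correct as the rate approaches
zero (mean → 1). Identical config and seed give byte-identical output.

What the generator does **not** emulate: duplicate or delayed reports,
reporter- or institution-level clustering, drug co-administration (one drug
per report by default; a `multi_drug_prob` stress option draws a second
independent drug), dose, indication, and any dependence of severity or
outcome on the specific DEC. Passing tests therefore demonstrate the
pipeline's correctness and the methods' operating characteristics under
clean marginal structure, not robustness to the reporting biases of real
SRS data.

The recovery harness treats implants with ρ > 1 as positives and every other
scored DEC as a negative; implanted pairs that never reach the scored
universe count as missed. Sensitivity is undefined (None) under a null
configuration; the false-discovery proportion is 0 when nothing is flagged.

## Packaged reference tables

The `pvkit.fixtures` module ships transcriptions of a published study's
aggregate tables (per-drug report and serious counts, organ-class and
preferred-term event counts, four death cases, 206 consensus signals of which
73 are annotated off-label) plus its headline summary counts. Two derived
entries are labelled as such in their docstrings: the improved-or-recovered
count (15,727) is the unique integer consistent with the printed 99.18% of
15,857, and the "label map" used in off-label tests is reconstructed from the
published off-label annotations, not from real product labeling.

## Problem sizes and tolerances

The test suite and acceptance script use: 10,000 random fourfold tables
(cells 1..499) at relative tolerance 1e-9 for formula-oracle agreement;
all 12⁴ tables for the exhaustive invariants; 2,000 multinomial tables with
expected a ≈ 100 for CI coverage (bound 95% ± 1.5%); and, for parameter
recovery, 20 databases of 50,000 reports with 20 implants at rate ratio 5 —
baselines restricted to [0.004, 0.06] so every implanted cell has expected
a ≥ 10 and the rate ratio survives renormalization — requiring mean consensus
sensitivity ≥ 0.9, plus 5 null databases checking that the consensus flag
rate does not exceed any single method's. Monte-Carlo tolerances elsewhere
(events-per-report ratio 2%, implant rate-ratio recovery 10%) reflect
binomial error at those sample sizes.

## Limitations

Signal thresholds are the classical heuristics; no multiplicity control or
Bayesian shrinkage (BCPNN, EBGM) is provided. Drug–drug interaction and
combination signals are out of scope. The pipeline takes reporter causality
assessments as given and performs no causality re-assessment. Reference
signal values from confidential source databases cannot be reproduced, since
the underlying fourfold counts are never published; the packaged signal table
is used structurally (consensus membership, off-label annotation), not
numerically.
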