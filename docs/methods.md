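# Methods

## Scope and data model

The package analyses spontaneous adverse-event reports in the FAERS
quarterly-extract form: five "$"-delimited tables per quarter (DEMO, DRUG,
REAC, OUTC, INDI) linked by a report-version identifier (`primaryid`),
with several versions of one case sharing a `caseid`. Files are decoded
as Latin-1 with replacement of undecodable bytes, because the public
extracts are not valid UTF-8. Rows that cannot be parsed (wrong field
count, invalid role or outcome code, blank mandatory identifiers) are
routed to a rejects log with file, line number and reason rather than
aborting; a missing mandatory column aborts with the column named.
Schema drift across quarters is absorbed by a schema profile that maps
each dialect's column names onto the canonical record fields; unknown
extra columns are ignored.

Age is normalized to years from the unit codes YR / DEC / MON / WK / DY /
HR (DEC ×10, MON ÷12, and so on); an unknown unit or an implausible
result (≤ 0 or ≥ 120 years) makes the age missing rather than rejecting
the report. Missing sex, country or weight become an explicit "unknown"
category and are never dropped, so descriptive tables can report unknown
strata.

**Deduplication.** Regulators re-publish a case whenever a follow-up
arrives. One report per case is kept: the version with the latest FDA
receipt date, ties broken by the largest `primaryid` (numeric comparison
where possible) — the conventional FAERS practice. The number of dropped
versions is reported in the run manifest so any headline cohort size is
auditable. Deduplication is idempotent and never increases the case count.

**Cohort.** The analysis cohort is every deduplicated report whose INDI
table carries a depression/MDD indication term (default
{"Depression", "Major depression"}, case-insensitive, configurable).
Exposure to a study drug means a primary- or secondary-suspect mention
whose verbatim name maps to a dictionary generic after normalization
(case-fold, trim, dosage and salt-suffix stripping; exact match only, no
fuzzy resolution). Concomitant and interacting mentions do not count —
suspect-only is the conservative pharmacovigilance convention; whether
the source analysis did the same is not stated, which is a recognized
uncertainty of the reconstruction. Unexposed cohort reports are kept:
they form the comparator cells (b, d) of every 2×2 table, and the cohort
size N is the grand total of all tables.

**Endpoints.** Reaction PTs map to four arrhythmia endpoints through
flat, pairwise-disjoint PT sets in the spirit of narrow-scope
standardised MedDRA queries. The licensed SMQ term lists cannot be
redistributed, so the shipped lists are editable placeholders
(`src/faerspv/data/endpoint_dictionary.yaml`); substituting licensed
lists is a one-file change. Disjointness is enforced at load time because
the endpoints are tabulated separately. A report may flag several
endpoints; endpoint flags are monotone in the PT set.

## Signal statistics

For each drug × endpoint pair, a = exposed ∧ event, b = unexposed ∧
event, c = exposed ∧ no event, d = the remainder, N = a+b+c+d. For a
fixed endpoint the event margin a+b is the endpoint's report total,
identical across drugs.

- PRR with Woolf-type CI on the log scale, multiplier 1.96; not estimable
  when a = 0 or b = 0.
- ROR = ad/bc with Woolf CI; not estimable on any zero cell. No
  continuity correction in this headline statistic (the pairwise module
  applies Haldane–Anscombe where needed).
- χ² with Yates continuity correction, clamped at zero. The corrected
  form is what reproduces the published statistics (e.g. 241.669 for the
  citalopram QT row; the uncorrected value is 242.9).
- IC in the single-shrinkage approximation log₂((a+½)/(E+½)),
  E = (a+b)(a+c)/N, with the asymmetric credibility-bound coefficients
  (3.3, 2) below and (2.4, 0.5) above. This form, not the exact posterior
  moment BCPNN, reproduces every published IC value and bound; the exact
  Bate posterior is out of scope.
- Signal criteria: a ≥ 3 ∧ PRR ≥ 2 ∧ χ² ≥ 4; a ≥ 3 ∧ ROR lower bound >
  1; IC025 > 0. Applied to the published cells these reproduce the
  published signal (bolding) pattern exactly, all 96 metric flags.
- Report rounding: ratios and IC to 2 decimals, χ² to 3; internal values
  stay at full precision.
- No multiple-testing adjustment anywhere, mirroring standard
  disproportionality practice; with 32 pairs × 3 criteria this inflates
  the family-wise false-flag rate, a known limitation of the method, not
  of the implementation.

## Pairwise contrasts

The "constituent ratio" contrast between drugs i and j within an endpoint
is operationalized as the odds ratio (a_i·c_j)/(a_j·c_i) — the
event-vs-non-event composition contrast of the two drugs' report sets.
This is the only definition that reproduces the published contrasts from
the contingency cells (all 20 printed ORs and CI bounds match to ±0.01).
CIs are Woolf on the log scale; any zero cell triggers the
Haldane–Anscombe +0.5 on all four cells, which keeps ORs finite and
preserves reciprocity. The matrix over k drugs has unit diagonal and
or(i,j)·or(j,i) = 1 to floating tolerance; the OR is reported as drug_i
relative to drug_j in row-major order (published prose sometimes flips
the reference direction).

The severity contrast compares, among a drug's endpoint-positive reports
with at least one outcome record, severe (death ∪ life-threatening)
against non-severe outcomes. "Severe" is configurable but defaults to the
fatal-progression pair; hospitalization, disability and other serious
codes count as non-severe for this contrast. Reports with no outcome
records are outcome-unknown and excluded from the denominators — treating
them as non-severe would be an untestable assumption given how large
unknown strata are in this kind of data. Published severity ORs cannot be
recomputed from printed data (per-drug severe/non-severe counts are
unpublished), so this operationalization is validated only on synthetic
data with planted severity odds.

## Descriptive summaries

Per endpoint stratum: report count, median and IQR of age (years) and
weight (kg) over non-missing values with linear interpolation between
order statistics (the numpy default; stated because published quartiles
are not recomputable and only stability matters), and percentage
breakdowns (sex, region US/other/unknown, seriousness, and per-outcome
yes/no/unknown) that always include an explicit unknown row and sum to
100 within rounding. A report is "serious" iff it carries any outcome
code; for a single outcome, "no" means other codes are present but not
this one, "unknown" means no outcome records at all.

## Synthetic data generator

The generator emulates the statistical structure the estimators assume,
with ground truth known by construction: independent reports; one
primary-suspect drug per report drawn from a catalog of (name, marginal
share, synonyms) plus a background pool (40 pool drugs by default);
per-endpoint event indicators drawn with probability background_rate ×
planted reporting-rate ratio (a rate × ratio product above 1 is rejected
as ill-posed); endpoint PTs drawn uniformly within the endpoint's term
group so the grouping logic is exercised; 1–3 filler PTs from a fixed
50-term neutral vocabulary; one outcome code (or none) per report from a
configurable profile, with per-(drug, endpoint) severity overrides;
an indication term (depression share 0.9 by default); follow-up versions
emitted at the duplicate fraction (default 0.05) with a later receipt
date and larger version id, filed one quarter later where possible; and
a ~30% chance of an extra concomitant mention to exercise the
suspect-only exposure rule. Quarter assignment is uniform — quarterly
structure matters only to I/O, not to the statistics.

`study_like_config()` sets the catalog shares and endpoint background
rates to echo the observed composition of the 746,507-report cohort
(drug shares 3–11%, endpoint rates 0.08–0.36%) and plants the published
signal pattern (elevated ratios for citalopram/escitalopram/quetiapine,
depressed for duloxetine). Same config ⇒ byte-identical output files.

What the generator does **not** emulate: drug–drug interaction or masking
effects, real marginal distributions of country/weight/co-medication,
reporting-over-time trends, or correlated duplicate edits. Passing the
synthetic tests therefore validates the estimators and plumbing under
independence, not robustness to those real-data features.

Validation settings used by the test suite: estimator recovery is checked
one planted drug per database (share 0.03, background rate 0.01, 200,000
reports) so the comparator background stays null — planting several
ratios in one database contaminates the comparator margin and biases the
ROR away from the planted value, which is a property of the design, not
of the estimator. With all ratios at 1, the IC025 > 0 criterion flags
0.5% of 200 (drug, endpoint) pairs (≤ 5% expected for a lower 2.5%
credibility bound).

## Fidelity to the published source table

The packaged fixture carries the published (a, b, c, d) cells for all 32
drug × endpoint rows (each summing to 746,507) together with the printed
statistics and signal pattern. Recomputation reproduces 315 of the 320
printed numbers to printed precision and the full flag pattern. The five
exceptions are print defects, each contradicted by its own row's other
printed statistics:

| row | printed | recomputed | internal evidence |
|-----|---------|------------|-------------------|
| duloxetine / QT, PRR | 0.17 | 0.19 | equals the row's printed ROR 0.19 |
| venlafaxine / QT, χ² | 1.418 | 3.584 | cells give 3.584; printed value fits no statistic of this row |
| venlafaxine / AF, PRR upper CI | 1.81 | 1.18 | equals the row's printed ROR upper 1.18 (digit transposition) |
| sertraline / VA, χ² | 13.787 | 0.094 | printed PRR 0.95 is near-null; 13.787 is impossible |
| fluoxetine / VA, IC | −0.01 | +0.01 | printed PRR/ROR 1.01 > 1 imply a positive IC (sign slip at the rounding boundary) |

These cells are excluded from the regression comparison and asserted
against their recomputed values instead. One further anomaly is kept as
printed: the duloxetine QT row carries b = 2701, so its event margin
a+b = 2761 exceeds the 2671 shared by the other seven QT rows by exactly
90 while the row still sums to the grand total; the margin test asserts
the +90 deviation explicitly so the defect stays visible.

## Problem sizes

The test suite and analysis drivers use 200,000-report databases for
estimator recovery, 60,000 reports for null calibration, 120,000 for the
end-to-end synthetic run, and 2,000–20,000 for plumbing tests — sizes at
which the generator's vectorized sampling and the columnar pipeline run
in seconds while leaving the recovery intervals tight enough to be
informative.
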