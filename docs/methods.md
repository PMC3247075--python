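# Methods

## The census model

`srcensus` treats one forest plot — one outcome under one pair-wise
intervention comparison — as one candidate meta-analysis, irrespective of
whether the review authors elected to display a pooled result. A plot is
an *eligible* meta-analysis when, after cleaning, it contains data from at
least two distinct studies. All descriptive statistics (counts,
cross-tabulations, quantile tables) are computed over eligible
meta-analyses and the study records they contain. Because subgroups
within a plot need not be mutually exclusive and the same study may
contribute to many plots, study records are counted once per
meta-analysis appearance; no distinct-study view is attempted, since study
identifiers are not reliable keys across plots or reviews.

## Cleaning rules

Curation proceeds in a fixed order, each stage writing one row of a flow
ledger (records in, excluded, reason), with conservation enforced between
consecutive stages:

1. **Review-level exclusions** — protocols, withdrawn reviews,
   methodology-group reviews, each counted under its own reason.
2. **Phantom-record removal.** Legacy forest-plot software stored a fixed
   zero-pattern row for studies listed in a plot without contributing
   data: apparent sample size 2, with 0/1 events per arm (dichotomous),
   means and SDs of 0 with one participant per arm (continuous), or O−E
   and variance both 0. Only these exact patterns are removed; genuine
   sample-size-2 studies with any other pattern are kept. Generic
   payloads have no documented pattern; by analogy we treat estimate = 0
   with standard error = 0 as phantom, switchable off via
   `CurationConfig(generic_phantom_rule=False)`. The stricter continuous
   reading (any arm split summing to 2) is available as
   `continuous_any_split=True`.
3. **Within-plot deduplication.** The first occurrence of each study
   identifier in document order across subgroups is kept. Matching is
   exact string identity after trimming, so "Smith 2001a" and
   "Smith 2001b" are distinct — near-duplicates under variant labels are
   deliberately not chased.
4. **The ≥ 2-study rule**, then removal of reviews left with no eligible
   plot.

Phantoms are removed before deduplication so that a duplicated phantom
cannot shield a second occurrence; the final at-least-two-distinct-studies
test is invariant to this order, which is why the order is an internal
choice rather than a user switch. The pipeline is idempotent on its own
output, a property the test suite asserts on randomized databases.

Structural anomalies (sibling outcomes sharing a name, missing outcome
names, payload/data-type conflicts) are *detected and reported only*;
automatic repair is out of scope because such mistakes need human
judgement.

## Taxonomies and collapses

The three vocabularies (11 specialties; 15 active + 2 control intervention
categories; 23 outcome categories) ship as an editable YAML file. Outcomes
that could fall under several categories resolve to the category highest
on a configurable priority list; the packaged default places mortality and
morbidity categories first and the broad sign/symptom categories last, and
any reproduction work should state its own order explicitly since priority
ordering is a modelling choice, not a fact of the data.

Two collapse maps drive the stratified summaries. The five-way
intervention grouping sends (active, comparator) pairs to Pharm vs
Control/Placebo, Pharm vs Pharm, Pharm vs Non-Pharm (either direction),
Non-Pharm vs Control/Placebo, or Non-Pharm vs Non-Pharm; Control and
Placebo are kept distinct in the data (review authors may code placebo as
"control", so the distinction is noisy) but combined in this view. The
11-group outcome collapse merges resource use with hospital-stay/process
measures, and cause-specific mortality with major-morbidity and
mortality/morbidity-composite events; the remaining categories fall into
two residual groups, "semi-objective" (surgical/device success,
withdrawals/dropouts, internal structure, external structure) and
"subjective" (quality of life, pain, mental health, mixed composites,
consumption, satisfaction). This residual membership is not arbitrary: it
is the unique assignment under which the collapsed group sizes re-sum the
published one-way outcome margins, and the test suite pins it. The
catch-all "Other" category has no natural residual and is assigned to the
subjective group by convention.

## Census statistics

- **Quantiles** use linear interpolation between order statistics at
  position `(n−1)p + 1` (numpy's default). On integer count data this
  yields integer medians and quartiles, matching how such tables are
  conventionally printed.
- **Percent rendering** supports two dialects seen in published census
  tables: `integer-floor-label` (0 → "0%", nonzero below 1% → "<1%", else
  nearest integer, half away from zero) and `one-decimal-small` (values
  below 1% printed with one decimal). Rendered percentages need not sum
  to 100; the underlying counts always re-sum exactly, and the cross-tab
  type enforces row/column/grand-total conservation on every input.
- **The rank-sum test** enumerates the exact tie-aware null distribution
  of the Mann-Whitney U over all C(n, n₁) assignments of pooled mid-ranks
  when n₁+n₂ ≤ 20, and otherwise uses the normal approximation with
  tie-corrected variance and a 0.5 continuity correction. The two-sided
  exact p-value is the null probability of a |U − n₁n₂/2| deviation at
  least as large as observed. The approximation agrees with the reference
  asymptotic implementation (scipy's) to numerical precision; against the
  exact enumeration its absolute error on balanced 8+8 samples is
  typically a few thousandths but can slightly exceed 0.01 for mid-range
  p-values — users needing exact inference at small n should rely on the
  enumeration path, which is the default there. The convenience wrapper
  `compare_study_counts` contrasts studies-per-meta-analysis in one
  outcome group (all-cause mortality by default) against all others.

## The synthetic generator

The generator emulates the *marginal* statistical structure of a large
census of healthcare meta-analyses; it makes no attempt to model joint
structure beyond what the hierarchy imposes.

| quantity | default family | parameters | calibration target |
|---|---|---|---|
| comparisons/review | truncated Zipf | a = 2.0, support 1–23 | median 1, Q75 = 2, long tail |
| outcomes/comparison | 1 + neg. binomial | r = 0.45, mean 4.1, cap 68 | quartiles 1 / 3 / 6 |
| studies/plot | 2 + neg. binomial | r = 0.37, mean 2.85, cap 300 | median 3, Q75 = 6, Q90 = 10 |
| study sample size | log-normal, rounded | μ = ln 91, σ = 1.1586, min 2, cap 10⁶ | quartiles 44 / 91 / 210 |

σ is matched to the quartiles as (ln 210 − ln 44)/(2 · 0.6745); the
negative-binomial and Zipf parameters were fitted by grid search to the
target quantiles and then frozen. Data types are drawn with probabilities
proportional to 14886 : 6672 : 895 (dichotomous : continuous : mixed),
the mixed share split 70 : 30 between generic and O−E payloads — the
published margins do not separate them, so the split is an assumption.
Specialty, intervention-pair and outcome labels are drawn independently
from the published one-way margins; real databases certainly correlate
these dimensions, so stratified summaries on synthetic data have
homogeneous strata where real data would vary. Achieved tails are
slightly lighter than the targets (99th percentile of studies/plot ≈ 26
vs 28; integer rounding pulls the lower sample-size quartile to ≈ 41 vs
44); matching extreme maxima (e.g. million-participant studies) is
explicitly out of scope and capped by config.

Contamination is applied last and only to reviews that would survive the
review-level exclusions: with the configured per-plot probabilities, a
duplicate re-inserts an existing first-subgroup study at the end of a
later sibling subgroup (creating one if needed), then a phantom record —
matching the curation patterns exactly — is appended to the final
subgroup. Appending after all genuine rows guarantees that the recorded
ground-truth positions are exactly the positions curation removes, so
tests can assert set equality rather than mere counts. Genuine
dichotomous draws that would coincidentally produce the phantom pattern
(totals 1/1, events 0/0 — probability well under 10⁻⁴ under the defaults)
are nudged to a non-phantom pattern to keep that accounting exact.

Randomness uses one root seed with a `SeedSequence([seed, review_index])`
substream per review, so increasing `n_reviews` extends a database without
perturbing earlier reviews.

Default contamination and status rates (phantom 0.10 and duplicate 0.05
per plot; protocol 0.30, withdrawn 0.02, methodology 0.01 per review) are
round values chosen to exercise every exclusion path at realistic orders
of magnitude — protocols are a large minority of records in review
databases, withdrawn and methodology reviews are rare, and phantom rows
were common enough to warrant an explicit rule. They are conditions of
the test bed, not estimates.

## What passing tests do and do not show

Synthetic data validates the *mechanics* — parsing, invariants, ledger
conservation, classification algebra, quantile computation, exact
contamination recovery — and the self-consistency of the calibration
(clean generated databases reproduce the configured medians: 3 studies
per meta-analysis exactly at ≥ 2000 plots, sample-size median within 10%
of 91). It cannot validate the taxonomic judgement embedded in real
labels, the joint distributions of real databases, or near-duplicate
studies under variant identifiers, which exact-string deduplication
misses by design.

## Problem sizes

The default test suite and the acceptance script use 600-review clean
databases (≈ 6500 plots) for calibration recovery, 15–40-review databases
across ≥ 20 seeds for contamination accounting, and full enumeration up to
n = 16 for rank-sum cross-checks; these sizes give stable medians and
exhaust the combinatorial checks while keeping a complete run to well
under a minute.
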