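# srcensus

A census pipeline for hierarchical systematic-review databases.

Collections of systematic reviews of healthcare interventions store their
"data and analyses" sections in a deep hierarchy: each **review** contains
pair-wise intervention **comparisons**, each comparison contains
**outcomes** — where one outcome is one forest plot, the unit treated as a
candidate **meta-analysis** — and each plot contains one or more
**subgroups** of study-level results. Study results arrive in four shapes:
dichotomous event counts, continuous summaries (mean, SD, n per arm),
generic estimate/standard-error pairs, and observed-minus-expected ("O−E")
event counts with variance; the latter two are pooled as *mixed* outcome
data.

`srcensus` is for meta-epidemiologists who want to characterise such a
collection: how many meta-analyses there are, what they compare, what they
measure, and how small they are. It provides

- **a typed data model** with canonical JSON and flat-CSV interchange
  (`srcensus.model`),
- **eligibility and cleaning rules** with a full audit ledger
  (`srcensus.curation`): exclusion of protocols, withdrawn and
  methodology-group reviews; removal of *phantom* study records (the fixed
  zero-pattern rows with apparent sample size 2 that legacy forest-plot
  software stored for studies listed without data); first-occurrence
  deduplication within plots whose subgroups overlap; and the
  at-least-two-studies rule defining an eligible meta-analysis,
- **controlled vocabularies** — 11 medical specialties, 15 active + 2
  control intervention categories, 23 outcome categories with a priority
  order — and collapse maps onto the coarser groupings used in stratified
  summaries (`srcensus.taxonomy`),
- **a descriptive census engine** (`srcensus.census`): one-way counts,
  the 15 × 5 intervention cross-tabulation with margins, quantile summaries
  (linear interpolation at position `(n−1)p + 1`), two percent-rendering
  dialects, and a Wilcoxon rank-sum test that enumerates the exact
  tie-aware null distribution for `n₁+n₂ ≤ 20` and otherwise uses a
  tie-corrected, continuity-corrected normal approximation,
- **a calibrated synthetic generator** (`srcensus.synthetic`) emitting
  databases with the hierarchy above, heavy-tailed count distributions,
  log-normal sample sizes and census-calibrated category marginals, plus
  controlled contamination (phantoms, duplicates) with recorded ground
  truth — so the whole pipeline is testable without any proprietary data.

## Worked example

```sh
srcensus simulate --seed 1 --n-reviews 40 --out db.json
srcensus summarize db.json --out results/
```

The first command writes a 40-review synthetic database (421 forest plots,
2135 study records at this seed) plus a `db.truth.json` recording every
injected phantom and duplicate. The second curates it, validates the
labels and writes `table1.csv` … `table6.csv`. The curation flow summary
printed along the way:

```
Reviews
  exclude protocol: 40 in, 8 excluded (protocol)
  exclude withdrawn: 32 in, 0 excluded (withdrawn)
  exclude methodology review group: 32 in, 1 excluded (methodology review group)
  no eligible meta-analysis: 31 in, 0 excluded (no eligible meta-analysis)
  -> 31 retained
Meta-analyses
  in excluded reviews: 421 in, 61 excluded (review excluded)
  fewer than two studies: 360 in, 0 excluded (fewer than two studies after cleaning)
  -> 360 retained
Studies
  in excluded reviews: 2135 in, 295 excluded (review excluded)
  phantom records: 1840 in, 31 excluded (zero-pattern phantom record)
  within-plot duplicates: 1809 in, 12 excluded (duplicate study identifier)
  in ineligible plots: 1797 in, 0 excluded (plot had fewer than two studies)
  -> 1797 retained
```

Each ledger obeys conservation (records into a stage = records into the
previous stage minus its exclusions), and the 31 phantoms and 12
duplicates removed are exactly the ones listed in `db.truth.json`.

The same machinery is available as a library:

```python
import srcensus as sc

db, truth = sc.generate_database(sc.default_config(n_reviews=600, seed=13))
report = sc.select_eligible_meta_analyses(db)
groups = sc.grouped_quantiles(report.curated, "studies_per_meta_analysis",
                              grouping="data_type_group")
for g in groups:
    print(g.label, g.n, g.quantiles)
```

With the calibrated defaults the curated database has a median of 3
studies per meta-analysis (quartiles 2–6) and a median study sample size
near 91 participants — very small meta-analyses of modestly sized trials,
the regime the census machinery is designed to describe.

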