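# prlink

Probabilistic record linkage for person-level administrative records —
and a fully synthetic benchmark for studying how linkage quality responds
to dataset overlap and data-entry error.

Researchers who work with administrative data (vital statistics, social
services, health registries) routinely need to identify the same person
across two files that share no common key, only noisy identifiers: names,
birthdate, address.  `prlink` implements the standard probabilistic
pipeline end to end:

1. **standardize** — uppercase, strip punctuation, blank placeholder
   values (`BABY BOY`, all-zero identifiers), parse dates componentwise;
2. **block** — reduce A×B to candidate pairs whose first *or* last names
   are TF-IDF character-4-gram cosine neighbors (top 3, cosine ≥ 0.80,
   ties kept) and whose birth month and year agree exactly;
3. **compare** — turn each candidate pair into a 15-column Boolean
   vector (exact agreements, Jaro-Winkler ≥ 0.85 name similarity, street
   token overlap, missingness flags);
4. **score** — assign each pair a match probability from a
   grid-searched gradient-boosted tree classifier (learning rate
   {0.01, 0.1, 0.25} × depth {5, 10, 15} × trees {250…2000}, stratified
   5-fold CV, parsimony tie-breaks), threshold at 0.80 into a linkage,
   optionally ensemble several classifiers by mean probability or
   majority vote.

Because real linkage data is confidential, the package ships a
simulator: paired record tables with a known fraction of shared
individuals (the *overlap*) and a controlled fraction of rows degraded
by realistic errors (typos, month/day shifts, address changes, blanked
middle names), plus the ground-truth pair list.  Evaluation reports
confusion-matrix metrics, blocking retention, threshold sweeps
(0.40–0.95), and agreement between two linkage solutions.  See
`docs/methods.md` for the model, calibration and design choices.

## Worked example

```python
from prlink import run_linkage

manifest, result, report = run_linkage(
    {"simulation": {"n_rows": 5000, "overlap": 0.2, "error_rate": 0.2}, "seed": 11,
     "model": {"grid": {"learning_rate": [0.1], "max_depth": [5], "n_estimators": [200]}}}
)
print("stage counts:", manifest.stage_counts)
print(f"matched pairs: {len(result)} at threshold {result.threshold}")
for k, v in report.as_dict().items():
    print(f"{k}: {'NA' if v is None else round(v, 4)}")
```

prints

```
stage counts: {'records_a': 5000, 'records_b': 5000, 'candidate_pairs': 1283, 'feature_rows': 1283, 'training_pairs': 3771, 'matched_pairs': 787}
matched pairs: 787 at threshold 0.8
accuracy: 1.0
sensitivity: 1.0
specificity: 1.0
precision: 1.0
f1: 1.0
matches_in_block: 0.787
adjusted_sensitivity_primary: 0.787
adjusted_sensitivity_alt: 0.166
```

Reading it: the two 5,000-row tables share 1,000 true individuals, and
20% of rows per table carry an injected error.  Blocking keeps 1,283
candidate pairs, of which 787 are true pairs that survived blocking
(`matches_in_block` = 787/1000 ≈ 0.787 — errors that change the birth
month or garble both names knock a true pair out of the block, here
roughly `1 − (2·0.2 − 0.2²)·0.65`).  On the pairs the classifier
actually sees it is perfect (sensitivity = precision = 1.0 at the 0.80
threshold), so the end-to-end recall equals the blocking retention
(`adjusted_sensitivity_primary` = 0.787).

The same run is available from the shell:

```bash
prlink simulate --rows 5000 --overlap 0.2 --error 0.2 --seed 11 --out data/
prlink block --a data/table_a.csv --b data/table_b.csv --out pairs.csv
prlink run --config config.yaml --out results/
```

Every stage (simulate, clean, block, features, train, score, link,
evaluate, sweep, agree, grid-report, run) is a subcommand; all tabular
I/O is headered CSV, and `--batch-size` bounds memory via chunked
execution that is bit-identical to serial execution.

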