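# moodstab

Mood-stability monitoring from passively collected smartphone and
wristband data, as a tested, reusable pipeline:

1. **synth** — generate synthetic per-participant raw streams (call
   logs, screen on/off events, app-usage sessions, wristband
   minute-packets, PHQ-9 submissions) with configurable coupling between
   a latent mood trajectory and behavioral rates;
2. **ingest** — read and validate the JSON-lines stream schemas with
   canonical local-time handling;
3. **samples** — form two-period data samples from every run of three
   consecutive PHQ-9 submissions, apply the discard rules (each period
   ≥ 7 days, ≥ 3 effective days per stream per period) and assign
   Steady/Swing labels from the three scores;
4. **features** — extract the per-period feature battery (call counts,
   durations, caller entropy, call-hour circular statistics; screen
   sessions and clock-bin ratios; app-category durations, counts and
   entropies; sleep architecture; step counts per 3-hour bin; nightly
   heart-rate cosinor parameters) and aggregate each across the two
   periods into difference / mean / SD sample features;
5. **select** — L1-sparsity and tree-importance feature selection,
   re-fit inside every CV training fold;
6. **bench** — 6 data-type combinations × 5 classification tasks × 6
   classifiers (SVM, KNN, decision tree, naive Bayes, random forest,
   logistic regression) under stratified 10-fold cross-validation,
   reporting mean/SD accuracy and positive-class (Swing) recall.

## CLI

```bash
# generate a synthetic cohort (one directory of JSON-lines files per participant)
moodstab synth --n-per-scenario 4 --seed 1 --out data/

# labeled two-period samples
moodstab samples --in data/ --out samples.csv

# per-sample feature matrix + manifest
moodstab features --samples samples.csv --in data/ --out features.csv --manifest manifest.json

# classifier benchmark (report.json / report.csv / report.md)
moodstab bench --features features.csv --samples samples.csv --out report/

# everything at once, with provenance.json
moodstab run --config cfg.yaml
```

All thresholds (period length, effective-day rules, sleep-run bridging,
selection hyperparameters, CV folds, …) live in a single YAML config;
see `moodstab.config.RunConfig` for the defaults. Every stage is
deterministic given the config and seed.

## Layout

```
src/moodstab/
  synth.py          # synthetic cohort generator
  ingest.py         # JSON-lines stream readers + screen-event cleaning
  sampling.py       # sample formation, discard rules, labeling
  features/         # phone + wearable features, two-period aggregation
  select.py         # L1 and tree-based feature selection
  bench.py          # CV benchmark grid and reports
  config.py         # RunConfig (YAML) with paper-anchored defaults
  pipeline.py       # run_all orchestration + provenance
  cli.py            # click CLI
```
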