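# normkit

Intracranial EEG (icEEG) normative band-power mapping and per-subject
abnormality scoring, end to end:

1. **Synthetic cohorts** (`normkit.synth`) — seeded generators for
   multichannel 1/f signals with band-limited oscillations, line noise and
   injected artifact/spiking channels; seizure-annotated exam timelines;
   toy labelled parcellation volumes; channel coordinates with known true
   ROIs; resection masks; and a ground-truth record for oracle checks.
2. **Temporal selection** (`normkit.temporal`) — locate clean interictal
   periods under state / seizure-buffer / sampling-rate / post-implantation
   constraints, greedily place fixed-length segments (default 70 s, 3 per
   subject, ≥ 4 h apart), extract them with full metadata, and flag
   unsuitable channels (flatline, outlier power, non-1/f spectrum).
3. **Spatial localisation** (`normkit.spatial`) — assign each channel to
   its nearest same-hemisphere grey-matter ROI (default 5 mm limit,
   otherwise "n/a"), compute distances to an optional resection mask
   (resected if ≤ 5 mm), and emit the per-channel table.
4. **Cohort database** (`normkit.db`) — a validated JSON document store
   with the three-level schema (subject / epilepsy status, exam, treatment
   / channel, segment, seizure), constrained vocabularies, uniqueness
   rules and referential integrity. Only file locations are stored, never
   raw signals.
5. **Normative map** (`normkit.normative`) — exclude pathological and
   unsuitable channels, common-average re-reference, band-pass + notch
   filter, resample, compute relative band power (RBP) in five bands via
   Welch PSD, aggregate channel RBP to ROI level (mean, then log10),
   remove leave-one-out cohort outliers, and summarise mean/SD/n of
   log10(RBP) per (ROI, band) with ≥ 30 subjects per retained cell.
6. **Abnormality map** (`normkit.abnormality`) — z-score held-out subjects
   against the map (same metric config enforced by hash), take max |z|
   over bands per ROI, label ROIs resected when > 25% of their channels
   were resected, and compute D_RS (Mann–Whitney AUC separating resected
   from spared regional abnormality).

`normkit.pipeline` ties the stages together behind a single JSON config
with a file manifest and a step-trace that accounts for every channel.

## CLI

```sh
normkit simulate --config cohort.json --out DIR [--seed N] [--overwrite]
normkit select-segments --timeline T.json --recording R.h5 --policy P.json --out DIR
normkit localise --coords C.csv --parc P.nii [--mask M.nii] --gm-dist 5 --resect-dist 5 --out T.csv
normkit db init|add|query --db DIR ...
normkit run --config run.json --stages all --out DIR
normkit build-map --config run.json --out DIR     # = run --stages map
normkit score --config run.json --out DIR         # = run --stages score
```

Exit codes: 0 ok, 2 validation error, 3 missing-dependency error. A full
`run` executes simulate → select → localise → db → map → score and writes
`manifest.json` (SHA-256 of every artifact + config hash); identical
config and seed reproduce identical manifests.

Minimal run config (see `normkit.pipeline.RunConfig` for all keys):

```json
{
  "cohort": {"n_subjects": 42, "n_holdout": 10,
             "pathological_rois": {"17": 3.0}, "seed": 7},
  "policy": {"n_segments": 1},
  "min_n": 30
}
```

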