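# gazeskill

Laparoscopic skill-level detection from eye-tracking time series and task
video frames. The package implements the full pipeline:

1. **Scoring & labeling** — each peg-transfer trial gets an objective score
   (300 s cutoff − task duration − 17 s per dropped peg, floored at 0) and
   trials are split into *novice / intermediate / expert* by 1-D k-means
   over the scores.
2. **Time-series branch** — gaze coordinate series are linearly resampled to
   a common length, discriminative subsequences (shapelets) are extracted
   (information-gain / F-stat / Mood's-median quality, self-similar pruning),
   and each series is mapped to its vector of minimum Euclidean distances to
   the selected shapelets. A seven-learner heterogeneous ensemble (RBF-SVM,
   random forest, extra trees, MLP, AdaBoost, GBDT, histogram-GBDT) is fused
   by stacked generalization (logistic regression over out-of-fold class
   probabilities) or majority voting.
3. **Image branch** — frames are extracted from per-trial directories with
   class-balanced capture rates and classified by a small CPU-friendly
   conv-feature + 3-layer fully-connected model (an Inception-ResNet-v2
   backbone slot exists but needs a deep-learning runtime).
4. **Fusion** — both branches' 3-class probability vectors are concatenated
   and combined by an extreme learning machine (tanh activation, 20 hidden
   nodes, pseudo-inverse output weights).

A seeded synthetic-data generator (`gazeskill.synthgen`) produces complete
datasets — gaze CSVs with planted class-specific motifs, trial metadata whose
scores cluster by class, and peg-board frames whose positional jitter shrinks
with skill — so every stage is testable without real recordings.

## CLI

```sh
# generate a synthetic dataset (gaze.csv, meta.csv, frames/, manifest.json)
gazeskill simulate --seed 1 --n-per-class 10 --out data/demo

# full pipeline: label -> shapelets -> ensemble, frames -> CNN, ELM fusion
gazeskill run --data data/demo --seed 1 --n-runs 5 --out results/report.json
gazeskill report --report results/report.json

# or stage by stage
gazeskill label     --data data/demo --out results/labels.csv
gazeskill shapelets --data data/demo --labels results/labels.csv \
                    --out-shapelets results/shapelets.csv \
                    --out-features results/features.csv
gazeskill train-ts  --features results/features.csv --labels results/labels.csv \
                    --out results/ts_preds.csv
gazeskill train-img --data data/demo --labels results/labels.csv \
                    --out results/img_preds.csv
gazeskill fuse      --ts-preds results/ts_preds.csv --img-preds results/img_preds.csv \
                    --labels results/labels.csv --out results/fused.csv
```

`run` accepts a YAML/JSON config (`--config`) with keys such as
`resample_len`, `shapelet_k`, `max_candidates`, `ensemble_mode`,
`image_epochs`, `elm_hidden`, `train_fraction`. Reports embed the master
seed and a config hash; two runs with the same seed are byte-identical.

## Layout

| module | role |
| --- | --- |
| `gazeskill.gaze_io` | gaze/metadata CSV I/O, detection-rate quality filter |
| `gazeskill.labeling` | peg-transfer score, k-means skill labels |
| `gazeskill.timeseries` | resampling, shapelet extraction & transform |
| `gazeskill.ensemble` | seven base learners, stacking / majority vote |
| `gazeskill.imaging` | frame extraction, capture-rate balancing, image model |
| `gazeskill.fusion` | ELM late fusion, confusion-matrix accuracy |
| `gazeskill.synthgen` | seeded synthetic datasets with planted structure |
| `gazeskill.pipeline` / `gazeskill.cli` | orchestration and command line |
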