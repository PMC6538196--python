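# occludecode

A desk-scale, fully synthetic re-implementation of a time-resolved MEG
decoding study of object recognition under occlusion. Every stage of the
computational pipeline is exercisable without any external data:

- **`occludecode.synthgen`** — multi-subject epoched sensor-data simulator
  (4 objects × 3 occlusion levels × mask/no-mask, 306-sensor triplet
  layout, condition-specific response envelopes with preset onset/peak
  latencies, sequential vs sustained spatial codes, AR(1) + white noise),
  plus a behavioral trial simulator and an HDF5 container.
- **`occludecode.stimuli`** — controlled occluded-stimulus synthesis:
  parametric silhouettes, front/back circular occluders targeted at a
  nominal occlusion fraction, and a Gabor/Gist low-level-feature control
  check.
- **`occludecode.decoding`** — baseline normalization + 20 Hz smoothing,
  pairwise linear-SVM decoding per time point (numba-accelerated dual
  coordinate descent), condition time-courses, temporal generalization
  matrices, cross-condition generalization, sensor-triplet maps.
- **`occludecode.inference`** — Wilcoxon sign-rank (exact null for n ≤ 25),
  Benjamini–Hochberg FDR, onset (10-consecutive-ms rule) and peak latency,
  leave-one-subject-out jackknife, paired curve comparison, and
  diagonal-asymmetry summaries for generalization matrices.
- **`occludecode.rsa`** — representational dissimilarity matrices,
  model–brain correlation time-courses, time-bin RDMs, semipartial variance
  partitioning, split-half replicability.
- **`occludecode.model`** — toy folded recurrent convolutional network in
  pure NumPy (weight-shared residual iterations, readout stages, exact
  fold/unfold equivalence, toy training, leave-one-level-out evaluation,
  confusion-matrix comparison).
- **`occludecode.pipeline` / CLI** — configuration validation and
  end-to-end orchestration.

## CLI

```bash
occludecode simulate --seed 7 --out data.h5            # desk-scale dataset
occludecode stimgen  --seed 7 --m 4 --out stimuli/     # image set
occludecode decode   --in data.h5 --analysis timecourse --occlusion 0 \
                     --reps 20 --window -100 350 --seed 1 --out curve.csv
occludecode run-all  --config cfg.yaml                 # full pipeline
```

A minimal `cfg.yaml`:

```yaml
seed: 7
scale: desk
occlusions: [0, 60]
n_repetitions: 20
window_ms: [-100, 350]
```

## Notes

- Sampled scales: simulator defaults are full scale (15 subjects, 306
  sensors, 64 trials/condition, 1 kHz); `desk_settings()` provides the
  CI-scale variant (8 subjects, 30 sensors, 16 trials, 500 Hz). The
  full-scale 5-D array is ~25 GB and is used as a metadata contract only.
- All randomness flows through explicit integer seeds and a counter-based
  fan-out (`numpy` `SeedSequence` spawn keys), so any unit of work is
  reproducible in isolation.
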