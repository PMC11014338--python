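# cardiovib

Multi-frequency cardiac vibration analysis in Python: a fully-annotated
simulator of composite chest-wall vibration recordings, zero-phase band
decomposition with EMD cross-validation, R-wave-anchored cycle segmentation,
automatic S1/S2 heart-sound labeling, and a compact 1D-CNN coordinate
regressor (pure NumPy, no deep-learning framework required) that localizes
ten fiducial points per cardiac cycle, together with the matching
evaluation protocol.

## What it does

- **`cardiovib.simulate`** — renders synthetic two-channel recordings
  (reference ECG + composite vibration at 2 kHz). The vibration channel is a
  DC offset plus three band-limited Gabor-atom modes (1–5 Hz volume change,
  5–30 Hz valve/contraction fiducials, 20–200 Hz heart sounds) plus baseline
  wander and Gaussian noise. Every recording carries its ground-truth event
  schedule, R times and per-mode component traces, and is bit-reproducible
  from its config.
- **`cardiovib.bands`** — zero-phase (forward–backward) second-order
  Butterworth band-passes into the canonical ECG / ULF-SCG / SCG / PCG
  bands, plus cubic-spline-sifting EMD and IMF-to-band matching by absolute
  Pearson correlation.
- **`cardiovib.segment`** — Pan–Tompkins-style R-peak detection, truncation
  of all bands into fixed-length 2048-sample `[R_i, R_{i+1})` segments
  (tail zero-padding), label attachment, a curvature labeling aid, and
  per-cycle ULF crest/trough (WC/WT) extraction.
- **`cardiovib.pcg`** — Shannon-energy envelopes and k-means phase
  clustering to auto-label S1/S2, plus paired position-correlation
  statistics.
- **`cardiovib.cnn`** — the seven reference conv-channel layouts (depth 6,
  kernel 3, maxpool 2/2, FC 1024→512→1 at input 2048), smooth-L1 training
  with Adam, plateau early stopping with best-weight restoration, and a
  3–10-layer depth sweep. Implemented in NumPy with explicit backprop;
  single-threaded deterministic given a seed.
- **`cardiovib.evaluate`** — R², MAE, RMSE, sample↔millisecond conversion,
  10-repeat random 70/30 split testing, 5-fold cross-validation, and the
  aggregation conventions (n−1 sample SD with truncated display; feature
  averaging after excluding the two hard diastolic features RE/RF).
- **`cardiovib.reference`** — published per-feature reference results used
  to verify the aggregation conventions and to pick per-feature structures.

## CLI

```bash
cardiovib simulate --config cfg.yaml --seed 7 --out rec.csv   # + rec.annotations.csv
cardiovib bands    --in rec.csv --out bands/                  # one CSV per band
cardiovib emd      --in rec.csv --imfs imfs.csv
cardiovib segment  --in rec.csv --annotations rec.annotations.csv --out ds.h5
cardiovib label-pcg --in rec.csv --out s1s2.csv
cardiovib train    --dataset ds.h5 --feature AO --structure 2 --seed 0 --out ao.npz
cardiovib predict  --model ao.npz --dataset ds.h5 --out pred.csv
cardiovib evaluate --dataset ds.h5 --models models/ --out report/
```

`cfg.yaml` keys mirror `simulate.SimulationConfig` (e.g. `n_cycles`,
`mean_heart_rate_bpm`, `noise_sd`, `event_jitter_s`).

## Notes on conventions

- "Second-order" Butterworth refers to the design order before the
  forward–backward pass (effective fourth-order magnitude).
- Coordinates are 0-based sample indices; segments start exactly at the
  R-peak sample; cycles are half-open `[R_i, R_{i+1})`.
- Training labels are internally scaled (samples/100 by default) so the
  smooth-L1 knee engages near unit residuals; all reported metrics are in
  samples or milliseconds.
- The learning rate default is 1e-4; 1e-3 is also an accepted documented
  value (the source material reports both) and is what the tests use for
  speed.
- The reported optimal structure for S1 is ambiguous in the source material
  (1 vs 7); `reference.structure_for("S1", s1_choice=...)` forces an
  explicit choice.
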