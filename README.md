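# drowsnet

EEG drowsiness-level classification toolkit: a full pipeline from simulated
multichannel EEG/EOG sessions to 2-class (alert/drowsy) and 5-level
(VA/FA/NAS/SNEA/VS) classification with a hybrid spatio-temporal
convolutional / bidirectional-LSTM network, conventional band-power SVM
baselines, and spectral analyses.

## What's inside

- **`drowsnet.simulate`** — synthetic session generator: repeated one-minute
  "flight" trials each followed by a beep and a 10-s sleepiness (KSS 1–9)
  report window; band-limited oscillations whose per-region amplitudes track
  the drowsiness level, 1/f background noise, and biphasic blink artifacts
  coupled into frontal EEG and four EOG reference channels. Missed reports
  count as KSS 9.
- **`drowsnet.preprocess`** — 60 Hz notch, 1–50 Hz zero-phase order-2
  Butterworth band-pass, 1000→100 Hz decimation, EOG-referenced FastICA
  component rejection, segmentation into non-overlapping 1-s epochs
  (30 channels × 100 samples; 3600 epochs per one-hour session), KSS→class
  mapping, and within-trial 75/25 4-fold assignments.
- **`drowsnet.nn`** — a pure-NumPy deep-learning core (valid convolutions,
  batch-norm, ELU, channel pooling, dropout, LSTM cells with BPTT, Adam) and
  the classifier itself. With the full published parameterization the shape
  chain is `30×100 → 30×32×92 → 30×64×84 → 30×128×76 → 18×128×76 → 9×128×76
  → 3×256×76 → 1×256×76 → 512×76 → 512×76 → 256×76 → 256×1 → 128 → 64 → K`.
  All backward passes are validated against finite differences in the tests.
- **`drowsnet.train_eval`** — 50-epoch / batch-32 training with a
  lowest-training-loss checkpoint, k-fold and leave-one-subject-out
  cross-validation, column-normalized confusion matrices,
  accuracy/sensitivity/specificity (alert = positive class), paired t-tests.
- **`drowsnet.baselines`** — PSD-SVM and CCA-SVM comparators (band-power
  features, optional canonical-correlation feature selection, RBF SVM; all
  statistics fitted on training folds only).
- **`drowsnet.spectral`** — band power per state/level/channel (delta 1–4,
  theta 4–8, alpha 8–13, beta 13–30, gamma 30–50 Hz), in-band mean
  frequency (power-weighted spectral centroid), paired comparisons with
  Bonferroni correction.
- **`drowsnet.session_io` / `drowsnet.pipeline` / `drowsnet.cli`** — HDF5
  containers (bit-exact round-trips), minimal EDF export/import with an
  events CSV sidecar, declarative YAML-configured end-to-end runs with
  atomic artifact writes and config-hash logging.

## CLI

```bash
drowsnet simulate --seed 1 --n-trials 60 --fs 1000 --out session.h5
drowsnet preprocess session.h5 --out epochs.h5
drowsnet cv epochs.h5 --k 4 --scheme five_class --out results/cv
drowsnet baseline epochs.h5 --kind psd_svm --out results/psd
drowsnet analyze epochs.h5 --scheme two_class --out spectra.csv
drowsnet run --config config.yaml --seed 1 --out results/run
```

A minimal `config.yaml`:

```yaml
sim: {generator: separable, n_subjects: 2, n_trials: 12, fs: 200.0}
preprocess: {ica: false}
model: {size: small, scheme: five_class}
train: {epochs: 5, batch_size: 32}
eval: {mode: cv, k: 4}
seed: 1
```

## Notes

- The original study's recordings are not publicly deposited, so its
  real-data accuracies (0.87 two-class, 0.69 five-class) are not
  reproducible here; the synthetic generator instead provides controlled
  ground truth for property-based verification at reduced scale.
- Everything runs on one CPU; the network is NumPy end to end (no GPU
  framework required).
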