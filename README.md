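# speechscreen

A speech-based two-class screening pipeline, end to end:

- **MFCC feature extraction** built stage by stage from the mel-scale
  equations — pre-emphasis, overlapping frames, periodic Hann window, FFT
  power spectrum, triangular mel filter bank (`Mel(f) = C·log10(1 + f/f0)`
  with `C = 1000/log10(1 + 1000/f0)`, ≈2595 at f0 = 700 Hz), log energies,
  and a type-II DCT keeping 13 coefficients per frame. Default dialect:
  FFT window 2048, hop 512, 128 mel bands from 0 Hz to Nyquist.
- **A bidirectional LSTM classifier with additive temporal attention**
  (Bi-LSTM → LSTM → attention pooling → dense → dropout 0.6 → dense →
  softmax), implemented in pure NumPy with hand-written backprop, verified
  against finite differences. The default architecture has ~1.5 M
  trainable parameters.
- **Particle swarm optimisation** over discrete hyperparameter candidate
  sets (learning rate, batch size, momentum, layer units), with clamp-and-
  round decoding from a continuous index space.
- **Participant-level 60/20/20 splitting** (stratified, leakage-guarded),
  SGD-with-momentum training with early stopping on validation loss, and
  **segment-level evaluation**: confusion matrix, sensitivity/specificity/
  accuracy, ROC curve, and trapezoidal AUROC (identical to the rank-sum
  estimator).
- **A synthetic cohort generator**: seeded source-filter speech-like audio
  whose two classes differ in syllable rate, pause occurrence/length,
  formant shift, and pitch jitter, so the whole pipeline is testable
  without any clinical data.

## CLI

Every subcommand takes `--config` (a YAML file overriding the defaults in
`speechscreen.config.DEFAULT_CONFIG`) and `--seed`:

```sh
speechscreen simulate  --seed 0 --out runs/cohort          # synthetic WAVs + manifest
speechscreen extract   --manifest runs/cohort/manifest.csv --out features.json
speechscreen optimize  --features features.json --manifest runs/cohort/manifest.csv
speechscreen train     --features features.json --manifest runs/cohort/manifest.csv
speechscreen evaluate  --model runs/train/model.npz --features features.json \
                       --manifest runs/cohort/manifest.csv
speechscreen run-all   --seed 0 --out runs/experiment      # full pipeline in one go
```

`run-all` writes the manifest, feature JSON, training history CSV, model
checkpoint, PSO trace (when enabled), metrics/ROC CSVs, and the resolved
config into the output directory; the whole run is reproducible from the
seed.

To run on real recordings instead of the generator, disable the cohort
section and point `data.manifest` at a CSV with columns
`participant_id,label,clip_path` referencing mono PCM WAV files.

## Layout

```
src/speechscreen/
  audio_io.py     WAV read/write/truncate, participant manifests
  mfcc.py         mel scale, extraction stages, segmentation, feature JSON
  synth.py        seeded two-class source-filter cohort generator
  pso.py          discrete-candidate particle swarm optimiser
  _nn.py          NumPy layers with exact backprop (LSTM, attention, ...)
  model.py        the Bi-LSTM-attention classifier and parameter counting
  training.py     splits, SGD training, PSO fitness, experiment runner
  evaluation.py   confusion/ROC/AUROC metrics and report I/O
  config.py       YAML config defaults and merging
  cli.py          click command group
```
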