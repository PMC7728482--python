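# mlecg

Multilead ECG classification toolkit: a QRS-protecting signal-cleaning
pipeline plus a dual-channel neural classifier whose convolution kernels are
constrained to the cross-shaped dependence structure of 12-lead ECG.

## The problem

A standard 12-lead electrocardiogram is a leads × time grid of voltages, but
it is not an image. A sample correlates with *adjacent samples on the same
lead* (the waveform in time) and with *other leads at the same instant* (the
same cardiac event seen from different projections) — while samples on
different leads at different times are essentially unrelated. A conventional
2-D CNN mixes all k² positions under each kernel and therefore learns from
the irrelevant diagonal neighbourhoods too.

This package implements:

* **Cross-masked convolution (MLCNN)** — k×k kernels whose weights are zero
  outside the cross through the centre (centre row = same lead across time,
  centre column = same instant across leads). A 5×5 kernel keeps 9 of 25
  weights; masked positions stay exactly zero through training.
* **A dual-channel network** — the masked CNN channel (three conv blocks,
  32/64/128 maps, batch-norm + ReLU + 2×2 max-pool, then a 256-unit dense
  layer) extracts waveform morphology from the full 12×1900 input; a
  bidirectional LSTM (128 hidden units per direction) extracts rhythm from
  the 1900-sample lead-II sequence. The two 256-d feature vectors are fused
  elementwise, `v = α·v₁ + (1−α)·v₂`, with α a *learnable* scalar
  (initialised at 0.7). A 512→128→64 head and softmax produce class
  probabilities; training minimises categorical cross-entropy with Adam.
* **A preprocessing pipeline** — running-median baseline removal (0.9 s
  window), FIR low-pass (40 Hz) + high-pass (2 Hz) band-limiting,
  Haar-wavelet R-peak detection (5-level DWT, detail bands 4–5), Q/S
  delineation, QRS-protected Kalman EMG removal (QRS samples restored
  bit-exact), 500→200 Hz polyphase resampling and 50/50-sample trimming to
  the 12×1900 network input.
* **Evaluation** — per-class one-vs-rest TP/TN/FP/FN and ACC/SE/SP
  percentages, with an internal-consistency validator.
* **A synthetic 12-lead generator** — five-Gaussian beats (P,Q,R,S,T)
  projected per lead, with baseline-wander, powerline and band-limited EMG
  noise and exact R-peak ground truth, so every stage is testable without
  clinical data.

## Worked example

```python
import numpy as np
from mlecg import (SynthConfig, generate_dataset, run_pipeline,
                   MLCNNBiLSTM, ModelConfig)

cfg = SynthConfig(noise_emg_amp=0.05, noise_baseline_amp=0.1,
                  noise_powerline_amp=0.02, seed=11)
classes = [{"heart_rate": 60.0},
           {"heart_rate": 150.0,
            "wave_params": {**cfg.wave_params, "R": (0.5, 0.0, 0.015)}}]
ds = generate_dataset(cfg, n_per_class=20, class_defs=classes)

x12, x2 = run_pipeline(ds.records)      # (40, 12, 1900), (40, 1900)
model = MLCNNBiLSTM(x12, x2, ds.labels, ModelConfig.small(seed=5))
res = model.fit()
print(res.summary())
```

prints (reduced desk-scale configuration):

```
                    MLCNN-BiLSTM Results
================================================================
channels:            both
input shape:         (12, 1900)
conv channels:       (4, 8, 16)  kernel (5, 5)
kernel mask:         full_cross (9/25 weights)
BiLSTM hidden:       16 per direction
classes:             2
trainable params:    132619
optimizer:           Adam  lr=0.001  batch=20
----------------------------------------------------------------
epochs run:          30
final loss:          0.0008
final train acc:     1.0000
fusion alpha:        init 0.700 -> learned 0.6928
================================================================
```

The two synthetic classes differ in heart rate (60 vs 150 bpm) and R-wave
amplitude (1.0 vs 0.5 mV); the scaled-down model separates them perfectly
within 30 epochs while the fusion weight α, updated by backpropagation,
moves from its 0.7 initialisation. `res.evaluate(x12, x2, ds.labels)`
returns the per-class ACC/SE/SP table and `res.featurize(...)` the
penultimate feature vectors (64-d under the full-size head).

A `mlecg` console script exposes the same steps as subcommands
(`synth`, `preprocess`, `rpeak`, `denoise`, `train`, `eval`, `featurize`,
`validate`).

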