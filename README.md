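# uesdist

Non-invasive estimation of the anterior-posterior (A-P) **upper esophageal
sphincter (UES) opening maximal distension** from tri-axial neck
accelerometry (high-resolution cervical auscultation, HRCA).

Insufficient UES distension during swallowing leads to pharyngeal residue
and aspiration risk, but its clinical measurement requires
videofluoroscopy (VFSS) — x-ray imaging that is not available at the
bedside. This package implements a sensor-based alternative for
researchers in dysphagia and biomedical signal processing: a denoising
chain for swallow vibration recordings, the VFSS landmark-geometry
protocol that defines the ground truth, an attention-masked
convolutional-recurrent network that regresses the distension ratio
directly from the cleaned signals, and a synthetic-swallow simulator that
makes every stage testable without clinical data.

## The estimator

A swallow is represented as T = 90 chunks of 66 samples x 3 axes (one
chunk = one 60 FPS video frame at the 4 kHz working rate). The network
computes

    y = FC( A_rnn ⊙ GRU( A_cnn ⊙ CNN(x_{1:T}) ) )

* `CNN`: per-chunk 1-D convolutions (16 length-5 filters per channel →
  48 channels, ReLU, max-pool 2/2, depthwise length-5 filter, ReLU),
  giving 48 x 27 = 1296 features per chunk (unpadded convolutions);
* `A_cnn`, `A_rnn`: attention gates of shape 90x1296 and 90x64 generated
  from the binary UES-opening mask by two-layer dense networks (2048
  hidden units, sigmoid output), focusing the model on the interval in
  which vibration energy correlates with distension;
* `GRU`: 3 stacked unidirectional layers of 64 units;
* `FC`: three 128-unit ReLU layers (20% dropout) and a sigmoid output
  unit, so the prediction is a ratio in (0,1) — the A-P distension
  normalized by the patient's C2-C4 vertebral segment length.

Training minimizes mean squared error with Adam; evaluation uses the
absolute percentage error APE = |prediction − truth| x 100 / truth,
pooled over k-fold cross-validation. The network, backpropagation and
optimizer are implemented directly on numpy (the full model holds ~252 M
parameters; training it needs roughly 4 GB of RAM).

## Worked example

```python
import numpy as np
from uesdist import model as M, workflow as wf
from uesdist.synthetic import SimulationSpec

# 200 simulated swallows, preprocessed and assembled end to end
spec = SimulationSpec(n_swallows=200, duration_range_ms=(350, 1500),
                      noise_sd=0.005, ar_sd=0.01, seed=11)
samples, _, _ = wf.simulate_model_inputs(spec)

train, test = samples[:160], samples[160:]
params, history = M.train(train, M.ModelConfig(epochs=15), seed=7)
preds = M.predict(test, params)
truth = np.array([s.target_ratio for s in test])
print(np.corrcoef(preds, truth)[0, 1], np.mean(M.ape(preds, truth)))
```

A seed-controlled run of this experiment (as performed by
`scripts/acceptance.py --seed 1`, which uses a shuffled 80/20 split of
the same dataset) reached held-out Pearson r = 0.89 against the planted
ratios with a mean APE of 18.5%, versus 48.1% for the untrained network;
77.5% of held-out swallows were within 30% APE. A single worked measurement: a
prediction of 0.35 against a measured ratio of 0.45 is an APE of 22.2%
(`M.ape(0.35, 0.45)`).

The command-line interface mirrors the pipeline:

```sh
uesdist simulate --n-swallows 50 --seed 0 --out data/
uesdist preprocess --input data/sw0000.txt --output clean/sw0000.txt
uesdist measure --landmarks 'data/*.landmarks.txt'
uesdist assemble --manifest data/manifest.csv --signal-dir clean/ --out ds.h5
uesdist train --dataset ds.h5 --epochs 15 --checkpoint model.h5
uesdist evaluate --dataset ds.h5 --folds 10
```

## Layout

| module | role |
|---|---|
| `uesdist.synthetic` | simulated swallows with planted distension ratios |
| `uesdist.preprocessing` | downsample → whiten → spline detrend → wavelet denoise |
| `uesdist.vfss` | VFSS landmark geometry and normalized distension |
| `uesdist.datasets` | chunking, UES-opening masks, dataset assembly |
| `uesdist.model` | the CNN + attention + GRU + FC regressor, Adam, APE |
| `uesdist.workflow` | fold planning, cross-validation, APE summaries |

`docs/methods.md` documents the model assumptions, parameter defaults,
and the limits of what the synthetic experiments demonstrate.
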