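# Methods

`uesdist` estimates the anterior-posterior (A-P) maximal distension of the
upper esophageal sphincter (UES) opening during a swallow, normalized by the
C2-C4 vertebral segment length, from tri-axial accelerometry recorded on the
anterior neck (high-resolution cervical auscultation, HRCA). This note
documents the model, the numerical choices, and what the synthetic test bed
does and does not establish.

## Measurement target

On lateral videofluoroscopy, trained raters measure the distension with a
landmark protocol: the C3 vertebral height (anterior-superior to
anterior-inferior corner) fixes the extent of the UES region; the segment
between the anterior-inferior corners of C2 and C4 serves as a
pseudo-vertical axis robust to head rotation and as a patient-height scalar;
the C3-height segment is re-anchored at the tracheal notch; the measurement
axis is the perpendicular to C2-C4 through a point of that anchored segment;
and the anterior/posterior UES wall points are projected onto it. The
normalized ratio is the maximal projected separation over the rated frames
(the frame of maximal hyoid displacement ±2-3 frames) divided by the C2-C4
length. All operations in `uesdist.vfss` are plain Euclidean geometry, so
results are invariant to rigid motion and, for the ratio, uniform scaling;
the test suite checks both to 1e-9. Pooling over frames uses the maximum
(it is a *maximal* distension); a mean reducer is available via
`normalized_max_distension(..., reducer="mean")` because rater protocols
vary on this point.

## Signal conditioning (`uesdist.preprocessing`)

Raw recordings are sampled at 20 kHz per axis. Four stages run in order:

1. **Downsampling to 4 kHz.** Linear-phase FIR low-pass (201 taps, cutoff at
   0.8x the target Nyquist, reflect-padded edges, group delay compensated)
   followed by keep-every-5th decimation. Linear phase preserves burst
   timing relative to video frames. A 3 kHz tone is attenuated by more than
   40 dB; passband tones are preserved within 1%.
2. **Device-noise whitening.** The sensor's zero-input response is modeled
   per channel by an autoregressive (AR) process fit with the modified
   covariance (forward-backward least-squares) method; the order (up to 10)
   is selected by BIC. The whitening FIR is the AR inverse
   `[1, -a1, ..., -ap]`. Stationarity (all AR roots strictly inside the
   unit circle) is asserted at construction. On noise generated by the
   fitted model the filter output has lag-1..10 autocorrelations below
   0.03 in magnitude.
3. **Spline detrending.** A least-squares spline of order 4 (cubic) with
   `floor(N * fl / fs)` uniformly spaced interior knots is fit and
   subtracted. `fl` (default 3 Hz, configurable per channel) bounds the
   frequency the spline can track: sub-`fl` drift is removed (>95% of a
   0.3 Hz sinusoid's energy) while a 70 Hz tone is preserved within 5%.
   The knot rule makes signals shorter than `fs / fl` samples (~334 ms at
   the defaults) unprocessable; the pipeline skips such swallows with a
   logged reason. The 3 Hz default is a documented stand-in: clinically
   used values are tuned per sensor axis.
4. **Wavelet denoising.** Discrete Meyer (`dmey`) multilevel decomposition,
   10 levels capped by signal length, soft thresholding of all detail
   bands at the universal threshold `sigma * sqrt(2 ln N)` with `sigma`
   the robust scale (MAD/0.6745) of the finest detail band. Soft
   thresholding necessarily shrinks in-band signal coefficients too; on a
   100 Hz tone at 0 dB SNR the measured gain is ~3.5 dB, and on simulated
   swallows the chain's end-to-end gain is dominated by the spline stage.

End-to-end denoising quality is scored with the scale-invariant SNR
(projection of the output onto the known clean burst), which is fair to
filters with non-unity passband gain such as the whitening stage.

## Network (`uesdist.model`)

Input: a swallow as T=90 chunks of 66 samples x 3 channels (66 samples =
one 60 FPS video frame at 4 kHz; 90 frames = the longest observed swallow,
1.5 s; shorter swallows are zero-padded at the tail, and the binary
UES-opening mask is zero on padding).

* **Chunk CNN:** 16 length-5 filters per channel (valid convolution, ReLU),
  max-pool (2/2), then one depthwise length-5 filter per channel (ReLU).
  With unpadded convolutions the feature length is
  48 x ((66-5+1)/2 - 5 + 1) = 48 x 27 = 1296 per chunk — the only reading
  consistent with the published 90 x 1296 attention mask ("same" padding
  would give 1584).
* **Attention generators:** two networks of identical layout (separate
  weights) take the binary UES-opening mask (length 90) through a
  2048-unit ReLU layer to sigmoid outputs of 90x1296 and 90x64, which
  gate the CNN feature sequence and the GRU output sequence elementwise.
  Gates are pure multiplicative factors in (0,1); no temporal
  renormalization is applied.
* **GRU stack:** 3 unidirectional layers, 64 units, zero initial state,
  per-step outputs of the last layer consumed.
* **Head:** the gated 90x64 sequence is flattened (5760) and passed through
  three 128-unit ReLU layers with 20% dropout after the first two, then a
  single sigmoid unit, so predictions live in (0,1) like the target ratio.

Training minimizes MSE with Adam (step size 1e-3, betas 0.9/0.999, batch
size 32 — standard defaults, exposed in `ModelConfig`). Everything
(forward, backprop, optimizer) is implemented on numpy in float32; a
float64 path exists and the backward pass is verified against central
finite differences along random parameter directions (elementwise checks
are unreliable at ReLU kinks, where zero-initialized biases of dead units
sit exactly). Initialization is seeded Glorot uniform; runs with the same
seed are bit-reproducible (init, shuffling, and dropout all derive from
one generator). The Adam update walks large arrays in slices to bound
temporary memory: the full model holds ~252 M parameters (~1 GB in
float32; ~4 GB including optimizer state and gradients), dominated by the
2048 x 116640 CNN-attention output layer.

## Synthetic test bed (`uesdist.synthetic`)

Each simulated swallow is a 3-channel 20 kHz recording composed of:

* a burst of 60-300 Hz band-passed noise (inside the reported swallow
  energy band), Tukey-windowed over the UES-open frame interval, with
  per-channel in-window RMS planted exactly as `a0 + a1 * ratio`
  (defaults 0.1 + 1.0*ratio) — a strictly monotone link between vibration
  energy and the distension ratio;
* motion drift: a 0.3 Hz sinusoid (amplitude 0.3) plus an integrated
  white-noise walk (std 0.1);
* AR(10) device noise with resonances placed above the swallow band
  (1.8-8 kHz at the raw rate, poles well inside the unit circle), so
  whitening leaves the burst nearly untouched, as expected of sensor
  electronics noise; innovation scale 0.02;
* white broadband noise (std 0.01).

Ratios are drawn uniformly from (0.2, 0.8) — a stand-in, since the
clinical distribution is unpublished beyond the ratio never exceeding
one. Each swallow carries a landmark set (pixel-quantized) consistent
with its planted ratio, so targets can be produced by the same geometry
protocol as clinical ground truth; quantization contributes ~0.01
absolute error at a ~100 px C2-C4 length.

What the simulator does **not** emulate: bolus-dependent spectral
structure, inter-patient variability, sensor placement effects, the
microphone channel, or rater disagreement. Passing recovery tests
therefore shows that the pipeline and estimator are implemented
correctly and can extract a planted energy-coded signal through the full
chain — not that clinical-grade accuracy is achieved on real swallows.

## Evaluation protocol (`uesdist.workflow`)

Swallows are shuffled into k equal folds (swallow-level, matching the
published protocol; sizes differ by at most one) and each fold is held
out once; per-swallow absolute percentage errors
(|prediction - truth| * 100 / truth) are pooled over folds and summarized
as mean ± SD and the fraction within 30% and 50%. Fold plans are seeded
and the train/test intersection is asserted empty.

## Problem sizes used in the shipped checks

The recovery checks train the full published architecture on a planted
dataset of 200 swallows (durations 350-1500 ms so every swallow clears
the spline knot rule; broadband and device noise at half the simulator
defaults, i.e. a low-noise condition) for 15 epochs with an 80/20
holdout — enough for the held-out Pearson r to pass 0.9 while keeping a
single-CPU run in minutes. The cross-validation pooling contract is
exercised with a constant-predictor training stub; full 10-fold training
of the 252 M-parameter model is supported through the CLI
(`uesdist evaluate`) but is not part of the default checks.

## Known limitations

* The clinical headline accuracy (mean APE ~27% on 434 patient swallows)
  is not reproducible here: it requires the undisclosed clinical dataset
  and trained weights. The package reports synthetic-recovery metrics
  instead.
* "Tenth-order Meyer wavelets" is read as the discrete Meyer family with
  up to 10 decomposition levels; both family and depth are configurable.
* Per-channel `fl` values and the clinical AR calibration recordings are
  not published; defaults are documented stand-ins.
* The GRU applies no explicit sequence-length masking; padded chunks carry
  zero signal and zero mask, matching the fixed-90 design.
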