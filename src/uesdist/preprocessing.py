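"""Four-stage denoising chain for swallowing accelerometry.

Raw tri-axial neck-accelerometer recordings (20 kHz) contain, besides the
swallow-induced vibrations, several structured noise sources: broadband
content above the band of interest, colored sensor ("device") noise,
low-frequency motion artifacts from head/neck movement, and residual
wideband noise.  The chain removes them in order:

1. anti-aliased downsampling to the 4 kHz working rate,
2. whitening of device noise with an FIR filter built from an
   autoregressive model of the sensor's zero-input response,
3. motion-artifact removal by subtracting a least-squares cubic spline
   (order 4) whose knot count scales as ``N * fl / fs``,
4. wavelet denoising (discrete Meyer family) with soft thresholding at
   the universal threshold ``sigma * sqrt(2 ln N)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy.interpolate import LSQUnivariateSpline

__all__ = [
    "RawRecording",
    "ARNoiseModel",
    "SplineConfig",
    "WaveletConfig",
    "CleanSignal",
    "downsample",
    "fit_ar_modified_covariance",
    "fit_device_noise_model",
    "fit_device_noise_models",
    "build_whitening_filter",
    "remove_motion_artifacts",
    "wavelet_denoise",
    "soft_threshold",
    "si_snr",
    "preprocess",
]

AXIS_LABELS = ("A-P", "S-I", "M-L")
RAW_FS = 20000.0
WORK_FS = 4000.0

#: number of taps of the linear-phase anti-aliasing FIR (odd -> integer delay)
_AA_NUMTAPS = 201
#: anti-aliasing cutoff as a fraction of the target Nyquist frequency
_AA_CUTOFF_FRACTION = 0.8


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Multichannel acceleration trace.

    ``samples`` has shape (channels, n); channel order follows
    ``channel_labels`` (anterior-posterior, superior-inferior,
    medial-lateral).
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_labels is None:
            n = self.samples.shape[0]
            self.channel_labels = AXIS_LABELS if n == 3 else tuple(
                f"ch{i}" for i in range(n))
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel label count does not match data")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class ARNoiseModel:
    """Autoregressive model of a sensor's zero-input (device) noise.

    Convention: ``x[n] = sum_i coefficients[i] * x[n-1-i] + e[n]``, so the
    whitening FIR is ``[1, -a1, ..., -ap]``.
    """

    coefficients: np.ndarray
    order: int
    selection_score: float = math.nan  # BIC at the selected order

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if self.order < 1 or self.order != self.coefficients.size:
            raise ValueError("order must be >= 1 and match the coefficients")
        if not self.is_stationary():
            raise ValueError("AR model is not stationary (root on/outside unit circle)")

    def ar_polynomial(self) -> np.ndarray:
        return np.concatenate(([1.0], -self.coefficients))

    def is_stationary(self) -> bool:
        roots = np.roots(self.ar_polynomial())
        return bool(np.all(np.abs(roots) < 1.0))


@dataclass
class SplineConfig:
    """Least-squares spline detrend stage.

    ``fl`` (the "lower sampling frequency", Hz) sets the knot density: a
    signal of N samples at rate fs gets ``floor(N * fl / fs)`` uniformly
    spaced interior knots, so the spline can only follow content slower
    than roughly fl.
    """

    fl: float = 3.0
    spline_order: int = 4  # i.e. cubic (polynomial degree 3)

    def __post_init__(self):
        if self.fl <= 0:
            raise ValueError("fl must be positive")
        if self.spline_order != 4:
            raise ValueError("only fourth-order (cubic) splines are supported")

    def knot_count(self, n_samples: int, fs: float) -> int:
        return int(math.floor(n_samples * self.fl / fs))


@dataclass
class WaveletConfig:
    family: str = "dmey"  # discrete Meyer
    levels: int = 10      # capped by signal length at run time

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")

    def universal_threshold(self, sigma: float, n: int) -> float:
        return float(sigma * math.sqrt(2.0 * math.log(n)))


@dataclass
class CleanSignal:
    """Denoised multichannel trace at the working rate, with provenance."""

    samples: np.ndarray
    fs: float
    applied_stages: list = field(default_factory=list)
    channel_labels: tuple = AXIS_LABELS

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


# ---------------------------------------------------------------------------
# stage 1: anti-aliased downsampling
# ---------------------------------------------------------------------------

def _antialias_taps(fs: float, target_fs: float) -> np.ndarray:
    cutoff = _AA_CUTOFF_FRACTION * (target_fs / 2.0)
    return sps.firwin(_AA_NUMTAPS, cutoff, fs=fs)


def downsample(rec: RawRecording, target_fs: float = WORK_FS) -> RawRecording:
    """Anti-aliased integer-factor decimation.

    A linear-phase FIR low-pass (cutoff below the target Nyquist) is
    applied with zero net group delay, then every ``fs/target_fs``-th
    sample is kept.  Only integer decimation ratios are supported
    (20 kHz -> 4 kHz is a factor of 5).
    """
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"decimation from {rec.fs} Hz to {target_fs} Hz is not an integer ratio"
        )
    ratio = int(round(ratio))
    if ratio == 1:
        return RawRecording(rec.samples.copy(), target_fs, rec.channel_labels)
    taps = _antialias_taps(rec.fs, target_fs)
    # symmetric odd-length FIR applied at zero net delay; edges are
    # reflect-padded so constants (and slow drift) pass undistorted
    half = len(taps) // 2
    filtered = np.stack([
        sps.fftconvolve(np.pad(ch, half, mode="reflect"), taps,
                        mode="same")[half:-half]
        for ch in rec.samples
    ])
    return RawRecording(filtered[:, ::ratio], target_fs, rec.channel_labels)


# ---------------------------------------------------------------------------
# stage 2: device-noise whitening
# ---------------------------------------------------------------------------

def fit_ar_modified_covariance(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Forward-backward least-squares (modified covariance) AR fit.

    Minimizes the summed forward and backward prediction error over the
    sample, returning ``(coefficients, residual_variance)`` in the
    ``x[n] = sum a_i x[n-i] + e`` convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n <= 3 * order:
        raise ValueError("signal too short for the requested AR order")
    p = order
    # forward prediction: x[t] from x[t-1..t-p], rows t = p..n-1
    xf = np.column_stack([x[p - 1 - i : n - 1 - i] for i in range(p)])
    yf = x[p:]
    # backward prediction: x[t] from x[t+1..t+p], rows t = 0..n-p-1
    xb = np.column_stack([x[1 + i : n - p + 1 + i] for i in range(p)])
    yb = x[: n - p]
    design = np.vstack([xf, xb])
    target = np.concatenate([yf, yb])
    coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coeffs
    return coeffs, float(np.mean(resid**2))


def fit_device_noise_model(zero_input, max_order: int = 10) -> ARNoiseModel:
    """Fit an AR model to a zero-input (device-noise) recording.

    Candidate orders 1..max_order are fit by the modified covariance
    method; the Bayesian information criterion selects the order.
    """
    if isinstance(zero_input, RawRecording):
        if zero_input.n_channels != 1:
            raise ValueError("pass a single channel; use fit_device_noise_models "
                             "for multichannel recordings")
        x = zero_input.samples[0]
    else:
        x = np.asarray(zero_input, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise ValueError("constant zero-input recording: degenerate AR fit")
    best = None
    for p in range(1, max_order + 1):
        coeffs, sigma2 = fit_ar_modified_covariance(x, p)
        if sigma2 <= 0:
            raise ValueError("degenerate AR fit (zero residual variance)")
        n_eff = 2 * (x.size - p)
        bic = n_eff * math.log(sigma2) + p * math.log(n_eff)
        if best is None or bic < best[0]:
            best = (bic, p, coeffs)
    bic, p, coeffs = best
    return ARNoiseModel(coefficients=coeffs, order=p, selection_score=bic)


def fit_device_noise_models(rec: RawRecording, max_order: int = 10) -> list:
    """One AR device-noise model per channel."""
    return [fit_device_noise_model(ch, max_order) for ch in rec.samples]


def build_whitening_filter(model: ARNoiseModel) -> np.ndarray:
    """FIR whitening taps ``[1, -a1, ..., -ap]`` (the AR inverse filter)."""
    if not model.is_stationary():
        raise ValueError("refusing to build a whitening filter for a non-stationary model")
    return model.ar_polynomial()


# ---------------------------------------------------------------------------
# stage 3: spline motion-artifact removal
# ---------------------------------------------------------------------------

def remove_motion_artifacts(x: np.ndarray, cfg: SplineConfig, fs: float) -> np.ndarray:
    """Subtract a least-squares cubic-spline fit of the slow trend.

    The spline has ``floor(N * fl / fs)`` uniformly spaced interior knots,
    so it tracks drift below roughly ``fl`` Hz and leaves the swallow band
    untouched; the detrended signal is the residual.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    knots = cfg.knot_count(n, fs)
    if knots < 1:
        raise ValueError(
            f"signal too short for spline detrending: floor({n}*{cfg.fl}/{fs}) < 1"
        )
    t = np.arange(n, dtype=float)
    interior = np.linspace(0.0, n - 1.0, knots + 2)[1:-1]
    spline = LSQUnivariateSpline(t, x, interior, k=cfg.spline_order - 1)
    return x - spline(t)


# ---------------------------------------------------------------------------
# stage 4: wavelet denoising
# ---------------------------------------------------------------------------

def wavelet_denoise(x: np.ndarray, cfg: WaveletConfig) -> np.ndarray:
    """Multilevel soft-threshold denoising with the universal threshold.

    sigma is the robust scale (MAD / 0.6745) of the finest detail band;
    all detail coefficients are soft-thresholded at sigma*sqrt(2 ln N).
    """
    x = np.asarray(x, dtype=float).ravel()
    wavelet = pywt.Wavelet(cfg.family)
    max_level = pywt.dwt_max_level(x.size, wavelet.dec_len)
    if max_level < 1:
        raise ValueError("signal too short for one wavelet decomposition step")
    levels = min(cfg.levels, max_level)
    coeffs = pywt.wavedec(x, wavelet, level=levels)
    sigma = float(np.median(np.abs(coeffs[-1]))) / 0.6745
    threshold = cfg.universal_threshold(sigma, x.size)
    coeffs[1:] = [soft_threshold(c, threshold) for c in coeffs[1:]]
    return pywt.waverec(coeffs, wavelet)[: x.size]


def soft_threshold(c: np.ndarray, threshold: float) -> np.ndarray:
    """Shrink each coefficient's magnitude by min(|c|, threshold)."""
    return np.sign(c) * np.maximum(np.abs(c) - threshold, 0.0)


def si_snr(x: np.ndarray, reference: np.ndarray) -> float:
    """Scale-invariant signal-to-noise ratio (dB) of x against a clean
    reference.

    The reference is scaled by its least-squares projection coefficient
    before computing the ratio, so filter stages with non-unity passband
    gain (e.g. whitening) are compared fairly.
    """
    x = np.asarray(x, dtype=float).ravel()
    reference = np.asarray(reference, dtype=float).ravel()
    denom = float(np.dot(reference, reference))
    if denom == 0:
        raise ValueError("reference signal is identically zero")
    alpha = float(np.dot(x, reference)) / denom
    err = x - alpha * reference
    return float(10.0 * np.log10((alpha**2 * denom) / np.sum(err**2)))


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def preprocess(
    rec: RawRecording,
    noise_models,
    spline_cfg: SplineConfig | None = None,
    wavelet_cfg: WaveletConfig | None = None,
    target_fs: float = WORK_FS,
) -> CleanSignal:
    """Run the four-stage chain: downsample, whiten, detrend, denoise.

    ``noise_models`` is one :class:`ARNoiseModel` per channel (a single
    model is broadcast to all channels); ``spline_cfg`` may likewise be a
    per-channel list, since the motion-artifact corner frequency is tuned
    per axis.  Provenance records the four stages in application order.
    """
    spline_cfg = spline_cfg or SplineConfig()
    wavelet_cfg = wavelet_cfg or WaveletConfig()
    if isinstance(noise_models, ARNoiseModel):
        noise_models = [noise_models] * rec.n_channels
    if len(noise_models) != rec.n_channels:
        raise ValueError(
            f"{len(noise_models)} noise models for {rec.n_channels} channels"
        )
    if isinstance(spline_cfg, SplineConfig):
        spline_cfgs = [spline_cfg] * rec.n_channels
    else:
        spline_cfgs = list(spline_cfg)
    if len(spline_cfgs) != rec.n_channels:
        raise ValueError(
            f"{len(spline_cfgs)} spline configs for {rec.n_channels} channels"
        )

    stages = []
    if rec.fs == target_fs:
        work = RawRecording(rec.samples.copy(), target_fs, rec.channel_labels)
        stages.append(f"downsample:skipped(already {target_fs:g} Hz)")
    else:
        work = downsample(rec, target_fs)
        stages.append(f"downsample:{rec.fs:g}->{target_fs:g} Hz")

    whitened = np.stack([
        sps.lfilter(build_whitening_filter(m), [1.0], ch)
        for m, ch in zip(noise_models, work.samples)
    ])
    stages.append("whiten:AR-inverse FIR per channel")

    detrended = np.stack([
        remove_motion_artifacts(ch, cfg, target_fs)
        for cfg, ch in zip(spline_cfgs, whitened)
    ])
    stages.append("spline_detrend:fl=" +
                  ",".join(f"{c.fl:g}" for c in spline_cfgs) + " Hz")

    denoised = np.stack([wavelet_denoise(ch, wavelet_cfg) for ch in detrended])
    stages.append(f"wavelet:{wavelet_cfg.family} soft universal threshold")

    return CleanSignal(denoised, target_fs, stages, rec.channel_labels)
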