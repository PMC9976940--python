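"""Synthetic swallow simulator with planted ground truth.

No public swallowing-accelerometry dataset with paired videofluoroscopy
ground truth exists, so every downstream stage is exercised on simulated
recordings whose generative parameters are known exactly:

* a band-limited vibration burst (60-300 Hz, inside the reported swallow
  energy band) confined to the UES-open frame window, amplitude-modulated
  by a Tukey window, with per-channel in-window RMS planted as a strictly
  monotone affine function ``a0 + a1 * truth_ratio`` of the normalized
  distension ratio;
* low-frequency motion drift: a 0.3 Hz sinusoid plus an integrated
  white-noise walk;
* AR-colored device noise (stationary AR(10) by default);
* broadband white noise.

Each synthetic swallow also carries a landmark set consistent with its
planted ratio, so the geometry protocol recovers the truth in a
round-trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocessing import RawRecording
from .vfss import LandmarkSet, c2c4_axis

__all__ = [
    "SimulationSpec",
    "SyntheticSwallow",
    "default_device_ar_coefficients",
    "generate_swallow",
    "generate_landmarks",
    "generate_dataset",
]


def default_device_ar_coefficients() -> np.ndarray:
    """Stationary AR(10) defaults for the colored device noise.

    Built from five conjugate pole pairs well inside the unit circle.
    The resonances sit above the swallow-vibration band (1.8-8 kHz at
    the 20 kHz raw rate), mimicking sensor/electronics coloration that
    leaves the 60-300 Hz burst band nearly untouched, so the whitening
    filter built from a refit of this noise distorts the burst little.
    """
    fs = 20000.0
    pole_spec = [(0.40, 4000.0), (0.35, 6000.0), (0.30, 8000.0),
                 (0.25, 2500.0), (0.20, 1800.0)]
    poles = []
    for radius, freq in pole_spec:
        angle = 2.0 * np.pi * freq / fs
        poles.extend([radius * np.exp(1j * angle), radius * np.exp(-1j * angle)])
    poly = np.real(np.poly(poles))          # [1, -a1, ..., -ap]
    coeffs = -poly[1:]
    assert np.all(np.abs(np.roots(np.concatenate(([1.0], -coeffs)))) < 1.0)
    return coeffs


@dataclass
class SimulationSpec:
    """Study conditions for the simulator (defaults mirror the clinical
    acquisition geometry: 20 kHz raw sampling, 4 kHz working rate, 60 FPS
    video, swallows up to 1.5 s)."""

    n_swallows: int = 434
    fs_raw: float = 20000.0
    fs_work: float = 4000.0
    fps: float = 60.0
    duration_range_ms: tuple = (300.0, 1500.0)
    distension_range: tuple = (0.2, 0.8)
    burst_gain: tuple = (0.1, 1.0)          # (a0, a1): in-window RMS = a0 + a1*ratio
    burst_band: tuple = (60.0, 300.0)       # Hz
    drift_freq: float = 0.3                 # Hz, sinusoidal component
    drift_amp: float = 0.3
    walk_sd: float = 0.1                    # std of the integrated-noise walk
    ar_coeffs: np.ndarray = field(default_factory=default_device_ar_coefficients)
    ar_sd: float = 0.02                     # innovation scale of device noise
    noise_sd: float = 0.01                  # broadband white noise
    seed: int = 0

    def __post_init__(self):
        self.ar_coeffs = np.asarray(self.ar_coeffs, dtype=float).ravel()
        lo, hi = self.distension_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("distension_range must lie strictly inside (0, 1)")
        if self.burst_gain[1] <= 0:
            raise ValueError("burst slope a1 must be positive (monotone planted effect)")
        if self.ar_coeffs.size > 10:
            raise ValueError("device-noise AR order must be <= 10")
        if self.ar_coeffs.size:
            roots = np.roots(np.concatenate(([1.0], -self.ar_coeffs)))
            if np.any(np.abs(roots) >= 1.0):
                raise ValueError("device-noise AR model must be stationary")
        if not self.drift_freq < 1.0:
            raise ValueError("drift_freq must be below 1 Hz")
        if self.duration_range_ms[0] > self.duration_range_ms[1]:
            raise ValueError("invalid duration range")


@dataclass
class SyntheticSwallow:
    recording: RawRecording
    truth_ratio: float
    onset_frame: int
    offset_frame: int
    fps: float
    landmark_set: LandmarkSet
    clean_burst: np.ndarray     # (3, n) noise/drift-free burst at fs_raw
    swallow_id: str = ""

    @property
    def n_frames(self) -> int:
        return int(self.recording.n_samples / self.recording.fs * self.fps)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def generate_landmarks(truth_ratio: float, c2c4_len: float = 100.0,
                       rotation: float = 0.0, seed: int = 0,
                       quantize: bool = False, frame_index: int = 0) -> LandmarkSet:
    """Place vertebral/tracheal/UES landmarks encoding a known ratio.

    The vertebral corners sit on a line rotated by ``rotation`` degrees
    from the image vertical; the UES wall points are separated by
    ``truth_ratio * c2c4_len`` along the perpendicular, so measuring the
    set with the geometry protocol recovers ``truth_ratio`` exactly
    (up to rounding when ``quantize`` snaps coordinates to integer
    pixels).
    """
    if c2c4_len <= 0:
        raise ValueError("c2c4_len must be positive")
    if not 0.0 <= truth_ratio < 1.0:
        raise ValueError("truth_ratio must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(rotation)
    # pseudo-vertical axis direction (image convention: +y is inferior)
    u = np.array([np.sin(theta), np.cos(theta)])
    perp = np.array([-u[1], u[0]])          # anterior direction
    origin = np.array([200.0, 100.0]) + rng.uniform(-5.0, 5.0, size=2)

    c2_ai = origin
    c4_ai = origin + c2c4_len * u
    c3_as = origin + 0.35 * c2c4_len * u
    c3_ai = origin + 0.60 * c2c4_len * u
    notch = origin + 0.45 * c2c4_len * u + 0.50 * c2c4_len * perp
    c3h = 0.25 * c2c4_len
    # wall points on the A-P line through the anchored segment's midpoint
    base = notch + 0.5 * c3h * u
    posterior = base - 0.15 * c2c4_len * perp
    anterior = posterior + truth_ratio * c2c4_len * perp

    points = dict(c2_ai=c2_ai, c3_as=c3_as, c3_ai=c3_ai, c4_ai=c4_ai,
                  tracheal_notch=notch, ues_anterior=anterior,
                  ues_posterior=posterior)
    if quantize:
        points = {k: np.round(v) for k, v in points.items()}
    return LandmarkSet(frame_index=frame_index, **points)


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def _frame_to_sample(frame: int, fs: float, fps: float) -> int:
    return int(round(frame * fs / fps))


def generate_swallow(spec: SimulationSpec, truth_ratio: float,
                     seed: int) -> SyntheticSwallow:
    """Simulate one swallow recording with a planted distension ratio.

    The three channels share the UES window but carry independent noise
    realizations.  Deterministic for a fixed (spec, truth_ratio, seed).
    """
    if not 0.0 < truth_ratio < 1.0:
        raise ValueError("truth_ratio must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)

    dur_ms = rng.uniform(*spec.duration_range_ms)
    n = int(dur_ms / 1000.0 * spec.fs_raw)          # floor of duration * fs
    n_frames = max(3, int(dur_ms / 1000.0 * spec.fps))

    # UES-open window strictly inside the frame span
    onset = int(rng.integers(max(1, int(0.15 * n_frames)),
                             max(2, int(0.40 * n_frames))))
    length = int(rng.integers(max(1, int(0.20 * n_frames)),
                              max(2, int(0.50 * n_frames))))
    offset = min(onset + length, n_frames - 2)
    offset = max(offset, onset)

    s0 = _frame_to_sample(onset, spec.fs_raw, spec.fps)
    s1 = min(_frame_to_sample(offset + 1, spec.fs_raw, spec.fps), n)
    target_rms = spec.burst_gain[0] + spec.burst_gain[1] * truth_ratio

    sos = sps.butter(4, spec.burst_band, btype="bandpass", fs=spec.fs_raw,
                     output="sos")
    t = np.arange(n) / spec.fs_raw
    window = sps.windows.tukey(s1 - s0, alpha=0.25)

    channels = []
    bursts = []
    for _c in range(3):
        burst = np.zeros(n)
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        seg = carrier[s0:s1] * window
        rms = float(np.sqrt(np.mean(seg**2)))
        if rms > 0:
            seg = seg * (target_rms / rms)          # exact planted in-window RMS
        burst[s0:s1] = seg
        bursts.append(burst)

        drift = spec.drift_amp * np.sin(
            2.0 * np.pi * spec.drift_freq * t + rng.uniform(0, 2 * np.pi))
        walk = np.cumsum(rng.standard_normal(n))
        walk_std = float(np.std(walk))
        if walk_std > 0 and spec.walk_sd > 0:
            drift = drift + walk * (spec.walk_sd / walk_std)

        if spec.ar_coeffs.size and spec.ar_sd > 0:
            device = sps.lfilter([1.0], np.concatenate(([1.0], -spec.ar_coeffs)),
                                 spec.ar_sd * rng.standard_normal(n))
        else:
            device = np.zeros(n)
        white = spec.noise_sd * rng.standard_normal(n)
        channels.append(burst + drift + device + white)

    landmarks = generate_landmarks(
        truth_ratio, c2c4_len=float(rng.uniform(90.0, 110.0)),
        rotation=float(rng.uniform(-15.0, 15.0)),
        seed=int(rng.integers(2**31)), quantize=True,
    )
    return SyntheticSwallow(
        recording=RawRecording(np.stack(channels), spec.fs_raw),
        truth_ratio=float(truth_ratio), onset_frame=onset, offset_frame=offset,
        fps=spec.fps, landmark_set=landmarks, clean_burst=np.stack(bursts),
    )


def generate_zero_input(spec: SimulationSpec, duration_s: float = 10.0,
                        seed: int = 0) -> RawRecording:
    """Simulated zero-input (device-noise-only) calibration recording:
    the AR-colored sensor noise plus broadband noise, no swallow, no
    drift -- the signal used to fit the whitening models."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * spec.fs_raw)
    chans = []
    for _c in range(3):
        if spec.ar_coeffs.size and spec.ar_sd > 0:
            dev = sps.lfilter([1.0], np.concatenate(([1.0], -spec.ar_coeffs)),
                              spec.ar_sd * rng.standard_normal(n))
        else:
            dev = np.zeros(n)
        chans.append(dev + spec.noise_sd * rng.standard_normal(n))
    return RawRecording(np.stack(chans), spec.fs_raw)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def generate_dataset(spec: SimulationSpec, out_dir=None):
    """Generate ``spec.n_swallows`` swallows plus a manifest.

    Truth ratios are drawn uniformly from ``spec.distension_range`` with
    the spec seed; per-swallow seeds are spawned deterministically.  With
    ``out_dir`` set, signals are written as 3-column delimited text and
    landmarks as named-point text files, and the manifest (CSV) is
    written alongside; otherwise everything stays in memory and the
    manifest's path column is empty.

    Returns ``(swallows, manifest)`` where ``manifest`` is a DataFrame
    with columns swallow_id, path, onset_frame, offset_frame, fps,
    truth_ratio.
    """
    if spec.n_swallows < 1:
        raise ValueError("n_swallows must be >= 1")
    from . import io as uio

    rng = np.random.default_rng(spec.seed)
    ratios = rng.uniform(*spec.distension_range, size=spec.n_swallows)
    child_seeds = rng.integers(2**31, size=spec.n_swallows)

    swallows, rows = [], []
    for i, (ratio, child) in enumerate(zip(ratios, child_seeds)):
        sw = generate_swallow(spec, float(ratio), int(child))
        sw.swallow_id = f"sw{i:04d}"
        path = ""
        if out_dir is not None:
            path = str(uio.write_signal(
                f"{out_dir}/{sw.swallow_id}.txt", sw.recording))
            uio.write_landmarks(f"{out_dir}/{sw.swallow_id}.landmarks.txt",
                                sw.landmark_set)
        rows.append(dict(swallow_id=sw.swallow_id, path=path,
                         onset_frame=sw.onset_frame, offset_frame=sw.offset_frame,
                         fps=sw.fps, truth_ratio=sw.truth_ratio))
        swallows.append(sw)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        uio.write_manifest(f"{out_dir}/manifest.csv", manifest)
    return swallows, manifest
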