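"""Model-input assembly: chunking, UES-opening masks, targets.

A cleaned 4 kHz swallow recording is cut into consecutive non-overlapping
chunks of 66 samples -- the span of exactly one videofluoroscopy frame at
60 FPS (floor(4000/60) = 66) -- and padded/truncated to a fixed sequence
of 90 chunks (the longest observed swallow, ~1.5 s).  Each swallow also
carries a binary mask over the 90 frames marking the UES-open interval
(inclusive of onset and offset frames) and a normalized distension target
in (0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .preprocessing import CleanSignal

__all__ = [
    "MAX_CHUNKS",
    "SwallowSample",
    "samples_per_frame",
    "chunk_signal",
    "build_ues_mask",
    "assemble",
]

log = logging.getLogger(__name__)

#: fixed sequence length: 90 VF frames at 60 FPS == 1.5 s
MAX_CHUNKS = 90


def samples_per_frame(fs: float, fps: float) -> int:
    """Signal samples spanned by one video frame: floor(fs / fps)."""
    if fs <= 0 or fps <= 0:
        raise ValueError("fs and fps must be positive")
    return int(fs // fps)


@dataclass
class SwallowSample:
    """Fixed-shape model input for one swallow.

    ``chunks``: (T, chunk_len, 3) float32, zero-padded past
    ``valid_chunks``; ``mask``: (T,) binary float32, zero on padding.
    """

    chunks: np.ndarray
    mask: np.ndarray
    target_ratio: float
    valid_chunks: int
    swallow_id: str = ""

    def __post_init__(self):
        self.chunks = np.asarray(self.chunks, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.float32)
        if self.chunks.ndim != 3 or self.chunks.shape[0] != self.mask.shape[0]:
            raise ValueError("chunks and mask disagree on sequence length")
        if not set(np.unique(self.mask)) <= {0.0, 1.0}:
            raise ValueError("mask entries must be binary")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target ratio must lie in (0, 1]")
        if np.any(self.mask[self.valid_chunks:] != 0):
            raise ValueError("mask must be zero on padded chunks")


def chunk_signal(clean: CleanSignal, fps: float = 60.0,
                 max_chunks: int = MAX_CHUNKS) -> tuple[np.ndarray, int]:
    """Cut a clean signal into per-frame chunks, pad/truncate to a fixed T.

    Returns ``(chunks, valid_chunks)`` with ``chunks`` of shape
    (max_chunks, samples_per_frame, channels).  A trailing partial chunk
    is dropped; sequences longer than ``max_chunks`` keep the earliest
    frames (with a warning), shorter ones are zero-padded at the tail.
    """
    if clean.n_samples == 0:
        raise ValueError("empty signal")
    spf = samples_per_frame(clean.fs, fps)
    data = clean.samples.T  # (n, channels)
    n_full = data.shape[0] // spf
    if n_full == 0:
        raise ValueError(f"signal shorter than one {spf}-sample chunk")
    if n_full > max_chunks:
        warnings.warn(
            f"swallow spans {n_full} frames; truncating to the first {max_chunks}",
            stacklevel=2,
        )
        n_full = max_chunks
    chunks = np.zeros((max_chunks, spf, data.shape[1]), dtype=np.float32)
    chunks[:n_full] = data[: n_full * spf].reshape(n_full, spf, data.shape[1])
    return chunks, n_full


def build_ues_mask(onset_frame: int, offset_frame: int,
                   T: int = MAX_CHUNKS) -> np.ndarray:
    """Binary mask with ones on frames onset..offset inclusive."""
    if not 0 <= onset_frame <= offset_frame < T:
        raise ValueError(
            f"invalid UES annotation: onset={onset_frame} offset={offset_frame} T={T}"
        )
    mask = np.zeros(T, dtype=np.float32)
    mask[onset_frame : offset_frame + 1] = 1.0
    return mask


def assemble(manifest, signals, targets=None, fps: float | None = None,
             max_chunks: int = MAX_CHUNKS):
    """Build one :class:`SwallowSample` per resolvable manifest row.

    ``signals`` maps swallow_id -> :class:`CleanSignal`; ``targets`` maps
    swallow_id -> normalized distension (defaults to the manifest's
    truth_ratio column).  Measurements above 1 are clipped to 1 with a
    warning; rows with missing data or out-of-range annotations are
    skipped with a logged reason.

    Returns ``(samples, skipped)`` where ``skipped`` is a list of
    (swallow_id, reason) pairs.
    """
    samples, skipped = [], []
    for row in manifest.itertuples(index=False):
        sid = row.swallow_id
        try:
            clean = signals[sid]
        except KeyError:
            skipped.append((sid, "no clean signal"))
            log.warning("skipping %s: no clean signal", sid)
            continue
        if targets is not None:
            try:
                target = float(targets[sid])
            except KeyError:
                skipped.append((sid, "no target measurement"))
                log.warning("skipping %s: no target measurement", sid)
                continue
        else:
            target = float(row.truth_ratio)
        if target > 1.0:
            warnings.warn(f"{sid}: measured ratio {target:.3f} > 1, clipping to 1",
                          stacklevel=2)
            target = 1.0
        if target <= 0.0:
            skipped.append((sid, f"non-positive target {target}"))
            log.warning("skipping %s: non-positive target", sid)
            continue
        row_fps = fps if fps is not None else float(row.fps)
        try:
            chunks, valid = chunk_signal(clean, row_fps, max_chunks)
            onset, offset = int(row.onset_frame), int(row.offset_frame)
            if offset >= valid:
                raise ValueError(f"offset frame {offset} outside {valid} valid chunks")
            mask = build_ues_mask(onset, offset, max_chunks)
        except ValueError as err:
            skipped.append((sid, str(err)))
            log.warning("skipping %s: %s", sid, err)
            continue
        samples.append(SwallowSample(chunks=chunks, mask=mask, target_ratio=target,
                                     valid_chunks=valid, swallow_id=sid))
    return samples, skipped
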