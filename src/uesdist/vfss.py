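"""Videofluoroscopy landmark geometry for UES distension measurement.

The anterior-posterior (A-P) distension of the open upper esophageal
sphincter is measured on lateral-view videofluoroscopy frames from a
small set of annotated landmarks:

1. the C3 vertebral height (anterior-superior to anterior-inferior
   corner) standardizes the superior/inferior extent of the UES region;
2. the C2-C4 segment (anterior-inferior corners of C2 and C4) serves as
   a pseudo-vertical axis, compensating for head rotation, and as an
   anatomical scalar for patient height;
3. the C3-height segment is re-anchored at the tracheal notch (junction
   of the superior border and posterior wall of the tracheal air
   column), extending inferiorly parallel to the C2-C4 axis;
4. the A-P measurement axis is the perpendicular to C2-C4 through a
   point of the anchored segment;
5-6. the anterior and posterior UES wall points are projected onto the
   A-P axis; their separation, divided by the C2-C4 length, is the
   normalized distension.

All operations are plain Euclidean geometry on abstract 2-D points, so
results are invariant to the image coordinate convention, to rigid
motion of the whole scene, and (for the normalized ratio) to uniform
scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkSet",
    "UESMeasurement",
    "c2c4_axis",
    "c3_height",
    "anchor_c3_segment",
    "ap_axis",
    "measure_distension",
    "measure_frame",
    "normalized_max_distension",
]


def _pt(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).ravel()
    if a.shape != (2,) or not np.all(np.isfinite(a)):
        raise ValueError(f"expected a finite 2-D point, got {p!r}")
    return a


@dataclass
class LandmarkSet:
    """Pixel landmarks of a single VF frame (image coordinates, y down)."""

    c2_ai: np.ndarray       # anterior-inferior corner of C2
    c3_as: np.ndarray       # anterior-superior corner of C3
    c3_ai: np.ndarray       # anterior-inferior corner of C3
    c4_ai: np.ndarray       # anterior-inferior corner of C4
    tracheal_notch: np.ndarray
    ues_anterior: np.ndarray
    ues_posterior: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        for name in ("c2_ai", "c3_as", "c3_ai", "c4_ai",
                     "tracheal_notch", "ues_anterior", "ues_posterior"):
            setattr(self, name, _pt(getattr(self, name)))
        if np.array_equal(self.c2_ai, self.c4_ai):
            raise ValueError("C2 and C4 corners coincide: pseudo-axis undefined")

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0),
                    scale: float = 1.0) -> "LandmarkSet":
        """Rigidly rotate/translate (and optionally scale) every landmark."""
        theta = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = _pt(translation)

        def f(p):
            return scale * (rot @ p) + shift

        return LandmarkSet(
            c2_ai=f(self.c2_ai), c3_as=f(self.c3_as), c3_ai=f(self.c3_ai),
            c4_ai=f(self.c4_ai), tracheal_notch=f(self.tracheal_notch),
            ues_anterior=f(self.ues_anterior), ues_posterior=f(self.ues_posterior),
            frame_index=self.frame_index,
        )


@dataclass
class UESMeasurement:
    distension_px: float
    c2c4_len_px: float
    normalized_ratio: float
    frame_index: int = 0

    def __post_init__(self):
        if self.distension_px < 0:
            raise ValueError("distension must be non-negative")


def c2c4_axis(lm: LandmarkSet) -> tuple[np.ndarray, float]:
    """Unit direction from the C2 to the C4 anterior-inferior corner, and
    the segment length (the patient-height scalar)."""
    delta = lm.c4_ai - lm.c2_ai
    length = float(np.hypot(*delta))
    if length == 0.0:
        raise ValueError("degenerate C2-C4 axis (coincident corners)")
    return delta / length, length


def c3_height(lm: LandmarkSet) -> float:
    """Euclidean C3 vertebral height (anterior-superior to anterior-inferior)."""
    h = float(np.hypot(*(lm.c3_ai - lm.c3_as)))
    if h == 0.0:
        raise ValueError("degenerate C3 height (coincident corners)")
    return h


def anchor_c3_segment(lm: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """C3-height segment re-anchored at the tracheal notch, running
    inferiorly (C2 -> C4 direction) parallel to the pseudo-vertical axis."""
    direction, _ = c2c4_axis(lm)
    height = c3_height(lm)
    start = lm.tracheal_notch
    return start, start + height * direction


def ap_axis(anchored: tuple[np.ndarray, np.ndarray], t: float,
            axis_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A-P measurement line: through the point at fraction ``t`` along the
    anchored segment, perpendicular to the C2-C4 direction."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    p0, p1 = _pt(anchored[0]), _pt(anchored[1])
    point = p0 + t * (p1 - p0)
    d = _pt(axis_dir)
    perp = np.array([-d[1], d[0]])
    perp = perp / np.hypot(*perp)
    return point, perp


def measure_distension(anterior, posterior, ap_line) -> float:
    """Absolute separation of the two wall points projected on the A-P
    direction (px)."""
    _, direction = ap_line
    return float(abs(np.dot(_pt(posterior) - _pt(anterior), _pt(direction))))


def measure_frame(lm: LandmarkSet, t: float = 0.5) -> UESMeasurement:
    """Run the full per-frame protocol on one landmark set."""
    direction, c2c4_len = c2c4_axis(lm)
    anchored = anchor_c3_segment(lm)
    line = ap_axis(anchored, t, direction)
    d = measure_distension(lm.ues_anterior, lm.ues_posterior, line)
    return UESMeasurement(
        distension_px=d, c2c4_len_px=c2c4_len,
        normalized_ratio=d / c2c4_len, frame_index=lm.frame_index,
    )


def normalized_max_distension(per_frame, c2c4_len: float,
                              reducer: str = "max") -> float:
    """Normalized maximal distension over the measured frames.

    In the measurement protocol judges rate the frame of maximal hyoid
    displacement plus 2-3 frames on either side (5-7 frames total); the
    maximal distension over those frames is divided by the C2-C4 length.
    ``reducer='mean'`` averages the frames instead.
    """
    if c2c4_len <= 0:
        raise ValueError("C2-C4 length must be positive")
    values = [m.distension_px if isinstance(m, UESMeasurement) else float(m)
              for m in per_frame]
    if not values:
        raise ValueError("at least one frame measurement is required")
    if reducer == "max":
        pooled = max(values)
    elif reducer == "mean":
        pooled = sum(values) / len(values)
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    return pooled / c2c4_len
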