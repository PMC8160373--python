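"""Facial region-of-interest processing: frames -> per-frame mean RGB trace.

The pipeline is: detect the face on the first frame, track it through the
stream, place three landmark points (left cheek A, right cheek B, chin-top C),
smooth them with a 0.3 s moving average, build a cheeks-and-nose rectangle
inset by 5% per side, and average each color channel over that rectangle per
frame.  Only the green channel is consumed downstream (blood absorbs green
most strongly), but all three means are kept for diagnostics.

Face detection / tracking / landmarking are pluggable backends.  The backends
shipped here operate on synthetic renderings (a face ellipse on a uniform
background); a production deployment would plug in a Haar-cascade detector,
a median-flow tracker and a learned landmark model behind the same protocols.

Conventions: pixel coordinates are 0-based with the origin at the top-left,
x rightward, y downward; boxes are half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

from .errors import DegenerateRoiError, SessionQualityError

__all__ = [
    "FrameStream",
    "RgbTrace",
    "FaceDetector",
    "SyntheticEllipseDetector",
    "detect_face",
    "track_roi",
    "smooth_landmarks",
    "build_roi",
    "extract_green_trace",
    "frames_to_trace",
]


@dataclass
class FrameStream:
    """An ordered stack of RGB frames (uint8, 256 tones per channel)."""

    frames: np.ndarray  # (n, height, width, 3) uint8
    fps: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n, h, w, 3)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass
class RgbTrace:
    """Per-frame channel means over the ROI, in tone units (0-255)."""

    t: np.ndarray  # seconds
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    fps: float
    interpolated: np.ndarray | None = None  # bool mask of interpolated frames

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_s": self.t, "r_mean": self.r, "g_mean": self.g, "b_mean": self.b}
        )

    @classmethod
    def from_frame(cls, df, fps: float) -> "RgbTrace":
        return cls(
            t=np.asarray(df["t_s"], float),
            r=np.asarray(df["r_mean"], float),
            g=np.asarray(df["g_mean"], float),
            b=np.asarray(df["b_mean"], float),
            fps=fps,
        )


class FaceDetector(Protocol):
    """Backend contract: return a face box ``(x0, y0, x1, y1)`` or None."""

    def detect(self, frame: np.ndarray) -> Optional[tuple[int, int, int, int]]: ...


class SyntheticEllipseDetector:
    """Detects the synthetic face as the connected blob differing from the
    background (sampled at the frame corners).  Returns its bounding box, or
    None when fewer than ``min_pixels`` face pixels are present."""

    def __init__(self, tol: int = 10, min_pixels: int = 50):
        self.tol = tol
        self.min_pixels = min_pixels

    def _mask(self, frame: np.ndarray) -> np.ndarray:
        corners = np.stack(
            [frame[0, 0], frame[0, -1], frame[-1, 0], frame[-1, -1]]
        ).astype(float)
        bg = np.median(corners, axis=0)
        return np.any(np.abs(frame.astype(float) - bg) > self.tol, axis=-1)

    def detect(self, frame: np.ndarray) -> Optional[tuple[int, int, int, int]]:
        mask = self._mask(frame)
        if mask.sum() < self.min_pixels:
            return None
        ys, xs = np.nonzero(mask)
        return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1

    def centroid(self, frame: np.ndarray) -> Optional[tuple[float, float]]:
        mask = self._mask(frame)
        if mask.sum() < self.min_pixels:
            return None
        ys, xs = np.nonzero(mask)
        return float(xs.mean()), float(ys.mean())


def detect_face(
    frame: np.ndarray, detector: FaceDetector | None = None
) -> Optional[tuple[int, int, int, int]]:
    """Detect the face bounding box on one frame; None means no face found."""
    if detector is None:
        detector = SyntheticEllipseDetector()
    return detector.detect(frame)


def track_roi(
    stream: FrameStream,
    initial_box: tuple[int, int, int, int],
    detector: FaceDetector | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Track the face box through the stream.

    Translates ``initial_box`` by the per-frame displacement of the face
    centroid (the synthetic stand-in for median-flow tracking).  Returns
    ``(boxes, missing)`` where ``boxes`` is an ``(n, 4)`` int array and
    ``missing`` flags frames where the face could not be located.
    """
    if detector is None:
        detector = SyntheticEllipseDetector()
    n = stream.n_frames
    boxes = np.zeros((n, 4), dtype=int)
    missing = np.zeros(n, dtype=bool)
    box0 = np.asarray(initial_box, dtype=float)

    c0 = None
    if hasattr(detector, "centroid"):
        c0 = detector.centroid(stream.frames[0])
    if c0 is None:
        det = detector.detect(stream.frames[0])
        if det is not None:
            c0 = ((det[0] + det[2]) / 2, (det[1] + det[3]) / 2)
    if c0 is None:
        raise SessionQualityError("no face on the first frame; cannot track")

    last_box = box0
    for i in range(n):
        frame = stream.frames[i]
        c = detector.centroid(frame) if hasattr(detector, "centroid") else None
        if c is None:
            det = detector.detect(frame)
            if det is None:
                missing[i] = True
                boxes[i] = np.rint(last_box).astype(int)
                continue
            c = ((det[0] + det[2]) / 2, (det[1] + det[3]) / 2)
        dx, dy = c[0] - c0[0], c[1] - c0[1]
        moved = box0 + np.array([dx, dy, dx, dy])
        moved[0::2] = np.clip(moved[0::2], 0, stream.width)
        moved[1::2] = np.clip(moved[1::2], 0, stream.height)
        boxes[i] = np.rint(moved).astype(int)
        last_box = moved
    return boxes, missing


def landmarks_from_box(boxes: np.ndarray) -> np.ndarray:
    """Synthetic landmark backend: place A (left cheek), B (right cheek) and
    C (chin-top) at fixed anatomical fractions of the tracked face box.

    Returns an ``(n, 3, 2)`` float array of (x, y) per landmark per frame.
    """
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    x0, y0, x1, y1 = boxes.T
    w, h = x1 - x0, y1 - y0
    a = np.stack([x0 + 0.18 * w, y0 + 0.50 * h], axis=1)
    b = np.stack([x0 + 0.82 * w, y0 + 0.50 * h], axis=1)
    c = np.stack([x0 + 0.50 * w, y0 + 0.78 * h], axis=1)
    return np.stack([a, b, c], axis=1)


def smooth_landmarks(
    track: np.ndarray, fps: float, window_s: float = 0.3
) -> np.ndarray:
    """Centered moving-average smoothing of a landmark track.

    The window is ``round(window_s * fps)`` frames forced odd (9 at 30 fps);
    at the edges the window shrinks symmetrically so constants are preserved.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    track = np.asarray(track, dtype=float)
    n = track.shape[0]
    w = int(round(window_s * fps))
    if w % 2 == 0:
        w += 1
    half = w // 2
    out = np.empty_like(track)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = track[i - k : i + k + 1].mean(axis=0)
    return out


def build_roi(
    a: Sequence[float], b: Sequence[float], c: Sequence[float], inset: float = 0.05
) -> tuple[float, float, float, float]:
    """Rectangle from the three landmarks: x spans A.x..B.x, y spans
    min(A.y, B.y)..C.y, inset by ``inset`` of the span per side."""
    ax, ay = a
    bx, by = b
    _, cy = c
    x_lo, x_hi = min(ax, bx), max(ax, bx)
    y_lo, y_hi = min(ay, by), cy
    w, h = x_hi - x_lo, y_hi - y_lo
    if w <= 0 or h <= 0:
        raise DegenerateRoiError(
            f"degenerate ROI: width={w:.3g}, height={h:.3g}"
        )
    return (x_lo + inset * w, y_lo + inset * h, x_hi - inset * w, y_hi - inset * h)


def extract_green_trace(
    stream: FrameStream,
    rois: np.ndarray,
    missing: np.ndarray | None = None,
    max_gap_s: float = 1.0,
) -> RgbTrace:
    """Mean of each color channel over the per-frame ROI.

    Frames flagged in ``missing`` get linearly interpolated channel means when
    the gap is at most ``max_gap_s``; longer gaps reject the session.
    """
    n = stream.n_frames
    rois = np.atleast_2d(np.asarray(rois))
    if rois.shape[0] == 1:
        rois = np.repeat(rois, n, axis=0)
    if rois.shape[0] != n:
        raise ValueError("need one ROI per frame")
    if missing is None:
        missing = np.zeros(n, dtype=bool)

    means = np.full((n, 3), np.nan)
    for i in range(n):
        if missing[i]:
            continue
        x0, y0, x1, y1 = rois[i]
        ix0, iy0 = int(np.floor(x0)), int(np.floor(y0))
        ix1, iy1 = int(np.ceil(x1)), int(np.ceil(y1))
        patch = stream.frames[i, iy0:iy1, ix0:ix1]
        if patch.size == 0:
            raise DegenerateRoiError(f"empty ROI on frame {i}")
        means[i] = patch.reshape(-1, 3).mean(axis=0)

    if missing.any():
        _check_gaps(missing, stream.fps, max_gap_s)
        idx = np.arange(n)
        good = ~missing
        for ch in range(3):
            means[missing, ch] = np.interp(idx[missing], idx[good], means[good, ch])

    t = np.arange(n) / stream.fps
    return RgbTrace(
        t=t, r=means[:, 0], g=means[:, 1], b=means[:, 2], fps=stream.fps,
        interpolated=missing.copy(),
    )


def _check_gaps(missing: np.ndarray, fps: float, max_gap_s: float) -> None:
    max_gap = int(round(max_gap_s * fps))
    run = 0
    for i, m in enumerate(missing):
        run = run + 1 if m else 0
        if run > max_gap or (m and (i == 0 or i == len(missing) - 1)):
            raise SessionQualityError(
                "face lost for longer than the interpolation limit "
                f"({max_gap_s:g} s) or at the session boundary"
            )


def frames_to_trace(
    stream: FrameStream,
    detector: FaceDetector | None = None,
    smooth_window_s: float = 0.3,
    inset: float = 0.05,
) -> RgbTrace:
    """Full stage-1-to-4 pipeline: detect, track, landmark, smooth, average."""
    if detector is None:
        detector = SyntheticEllipseDetector()
    first_box = None
    for i in range(stream.n_frames):
        first_box = detector.detect(stream.frames[i])
        if first_box is not None:
            break
    if first_box is None:
        raise SessionQualityError("no face found in any frame")
    boxes, missing = track_roi(stream, first_box, detector)
    lms = smooth_landmarks(landmarks_from_box(boxes), stream.fps, smooth_window_s)
    rois = np.array(
        [build_roi(lm[0], lm[1], lm[2], inset=inset) for lm in lms]
    )
    return extract_green_trace(stream, rois, missing=missing)
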