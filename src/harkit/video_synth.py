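"""Synthetic silhouette video: a textured articulated blob over a static scene.

Frames are rendered analytically (sums of sinusoids windowed by smooth
logistic edges) so sub-pixel motion is exact and differentiable — the
property optical-flow estimation needs.  The blob stands at a rest position
and, during an activity, translates along that activity's characteristic
display-space direction with a bounded back-and-forth excursion, returning
to rest at the end of the repetition.
"""

from __future__ import annotations

import numpy as np

from .archetypes import video_motion
from .errors import UnknownActivityError  # noqa: F401  (re-raised via video_motion)

_PHASE_LAG = np.pi / 4  # keeps the mid-repetition speed away from zero


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    key = tuple(shape)
    if key not in _GRID_CACHE:
        h, w = key
        y, x = np.mgrid[0:h, 0:w].astype(np.float64)
        bg = 22.0 + 8.0 * np.sin(2 * np.pi * x / 31.0) * np.sin(2 * np.pi * y / 37.0)
        _GRID_CACHE[key] = (x, y, bg)
    return _GRID_CACHE[key]


def _render_frame(shape: tuple[int, int], offset: tuple[float, float]) -> np.ndarray:
    """One grayscale frame (H, W) with the blob displaced by ``offset`` px.

    ``offset`` is (dx, dy) in image coordinates (x rightward, y downward).
    """
    h, w = shape
    x, y, bg = _grid(shape)
    cx = 0.52 * w + offset[0]
    cy = 0.55 * h + offset[1]
    a = x - cx
    b = y - cy
    bw, bh = 0.34 * w, 0.62 * h
    env = _sigmoid((bw / 2 - np.abs(a)) / 2.0) * _sigmoid((bh / 2 - np.abs(b)) / 2.0)
    tex = (110.0
           + 45.0 * np.sin(2 * np.pi * a / 13.0 + 1.1) * np.sin(2 * np.pi * b / 17.0 + 0.4)
           + 35.0 * np.sin(2 * np.pi * (a + b) / 11.0))
    return bg * (1.0 - env) + env * tex


def _excursion(p: np.ndarray | float, n_pulses: int) -> np.ndarray | float:
    """Normalized signed excursion along the motion axis; 0 at p=0 and p=1."""
    return np.sin(np.pi * p) * np.sin(n_pulses * np.pi * p + _PHASE_LAG)


def activity_offset(activity: str, p: float, frame_shape: tuple[int, int],
                    scale: float = 1.0) -> tuple[float, float]:
    """Blob displacement (dx, dy) at phase ``p`` of one repetition."""
    m = video_motion(activity)
    amp = scale * m["amplitude_frac"] * min(frame_shape)
    off = amp * _excursion(p, m["n_pulses"])
    theta = np.deg2rad(m["angle_deg"])
    # display-space CCW angle; image y grows downward
    return off * np.cos(theta), -off * np.sin(theta)


def render_silhouette_video(activity: str, duration: float,
                            frame_shape: tuple[int, int] = (144, 180),
                            fps: float = 25.0, scale: float = 1.0) -> np.ndarray:
    """Render one repetition as ``round(duration * fps)`` grayscale frames."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_frames = int(round(duration * fps))
    frames = np.empty((n_frames,) + tuple(frame_shape))
    for k in range(n_frames):
        p = (k / fps) / duration
        frames[k] = _render_frame(frame_shape, activity_offset(activity, p, frame_shape, scale))
    return frames


def static_clip(n_frames: int, frame_shape: tuple[int, int] = (144, 180)) -> np.ndarray:
    """Motionless filler (standing): every frame identical."""
    frame = _render_frame(frame_shape, (0.0, 0.0))
    return np.repeat(frame[None], n_frames, axis=0)


def translating_clip(n_frames: int, frame_shape: tuple[int, int],
                     angle_deg: float, speed_px: float) -> tuple[np.ndarray, tuple[float, float]]:
    """Pure uniform translation of the textured blob; ground truth returned.

    The blob moves ``speed_px`` pixels per frame at ``angle_deg`` (display
    CCW from +x).  Returns ``(frames, (dx, dy))`` with the per-frame
    displacement in image coordinates, for flow-recovery tests.
    """
    theta = np.deg2rad(angle_deg)
    dx, dy = speed_px * np.cos(theta), -speed_px * np.sin(theta)
    start = -0.5 * (n_frames - 1)
    frames = np.empty((n_frames,) + tuple(frame_shape))
    for k in range(n_frames):
        frames[k] = _render_frame(frame_shape, ((start + k) * dx, (start + k) * dy))
    return frames, (dx, dy)
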