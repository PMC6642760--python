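"""Synthetic multi-sensor cohort generation.

Emulates the statistical structure of a 20-subject activity-recognition
study: each subject performs a drawn number of repetitions of each of 12
elementary activities while four synchronized streams are recorded —
8-channel surface EMG (2 kHz), 64-sensel plantar pressure (100 Hz),
triaxial sternum acceleration (100 Hz) and grayscale silhouette video
(25 fps).  Every recording opens with a stationary lead-in (>= 10 s) used
downstream to estimate the accelerometer offset.

Each repetition is the activity's archetype template, time-warped to a
log-normally drawn duration, scaled by a subject-specific amplitude
multiplier, and buried in additive Gaussian noise; the result is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import archetypes as arch
from .archetypes import ACTIVITIES, activity_archetype, video_motion
from .errors import HarkitError
from .video_synth import _render_frame, activity_offset

#: Standing-load baseline for the pressure sensels (arbitrary force units).
PRESSURE_BASELINE = 0.6
#: Gravity-dominated accelerometer baseline (X forward, Y lateral, Z vertical).
ACC_BASELINE = np.array([0.12, -0.04, 1.00])

#: Median duration (s) and log-sd of each activity's log-normal duration model.
DEFAULT_DURATION_MODEL: dict[str, tuple[float, float]] = {
    "1a": (1.5, 0.16), "1b": (1.4, 0.16),
    "2a": (1.8, 0.16), "2b": (1.6, 0.16),
    "3a": (1.7, 0.16), "3b": (1.5, 0.16),
    "4a": (1.9, 0.16), "4b": (1.7, 0.16),
    "5a": (2.1, 0.16), "5b": (1.9, 0.16),
    "6a": (1.3, 0.14), "6b": (1.3, 0.14),
}

#: Additive noise scale per sensor, in archetype amplitude units (video in
#: 8-bit intensity levels).
DEFAULT_NOISE_SD: dict[str, float] = {
    "emg": 0.05, "pressure": 0.03, "acc": 0.03, "video": 2.0,
}

SENSOR_KEYS = ("emg", "pressure", "acc", "video")


def _noise_map(noise_sd) -> dict[str, float]:
    """Accept a scalar (scaled onto every sensor) or a per-sensor mapping."""
    if noise_sd is None:
        return dict(DEFAULT_NOISE_SD)
    if np.isscalar(noise_sd):
        s = float(noise_sd)
        return {"emg": s, "pressure": s, "acc": s, "video": 40.0 * s}
    out = dict(DEFAULT_NOISE_SD)
    out.update(noise_sd)
    return out


@dataclass
class CohortConfig:
    """Study conditions of the simulated cohort.

    Defaults follow the emulated study: 20 subjects, 12 activities with
    19-46 repetitions each, 2 kHz EMG, 100 Hz pressure and acceleration,
    25 fps video.  ``video_size`` is (width, height); the default 180x144
    is the desk-scale frame (the full 720x576 is available by config).
    """

    n_subjects: int = 20
    activities: tuple[str, ...] = ACTIVITIES
    reps_range: tuple[int, int] = (19, 46)
    duration_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_MODEL))
    noise_sd: Mapping[str, float] | float | None = None
    subject_scale_sd: float = 0.15
    seed: int = 0
    video_size: tuple[int, int] = (180, 144)
    emg_rate: float = 2000.0
    pressure_rate: float = 100.0
    acc_rate: float = 100.0
    video_rate: float = 25.0
    lead_in_s: float = 12.0
    tail_s: float = 2.0
    gap_range_s: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self):
        if tuple(self.activities) != ACTIVITIES:
            raise HarkitError(
                f"activities must be the 12 labels {ACTIVITIES}, got {self.activities}")
        lo, hi = self.reps_range
        if not (1 <= lo <= hi <= 100):
            raise HarkitError(f"reps_range must lie within [1, 100], got {self.reps_range}")
        for name in ("emg_rate", "pressure_rate", "acc_rate", "video_rate"):
            if getattr(self, name) <= 0:
                raise HarkitError(f"{name} must be positive")
        if self.n_subjects < 1:
            raise HarkitError("n_subjects must be >= 1")
        if self.lead_in_s < 10.0:
            raise HarkitError("lead_in_s must be >= 10 s (accelerometer offset window)")
        self.noise = _noise_map(self.noise_sd)

    @property
    def frame_shape(self) -> tuple[int, int]:
        w, h = self.video_size
        return (h, w)


@dataclass
class MultiSensorRecording:
    """One subject's synchronized raw streams.

    ``emg`` (8, n), ``pressure`` (64, n), ``acc`` (3, n) are float arrays
    (channels x samples); ``video`` is (n_frames, H, W) uint8.  All streams
    cover the common span [0, duration].
    """

    subject_id: str
    emg: np.ndarray
    pressure: np.ndarray
    acc: np.ndarray
    video: np.ndarray
    rates: dict[str, float]
    lead_in_s: float

    def __post_init__(self):
        if self.emg.shape[0] != 8:
            raise HarkitError("emg must have exactly 8 channels")
        if self.pressure.shape[0] != 64:
            raise HarkitError("pressure must have exactly 64 sensels")
        if self.acc.shape[0] != 3:
            raise HarkitError("acc must have exactly 3 channels")
        if self.lead_in_s < 10.0:
            raise HarkitError("stationary lead-in must be >= 10 s")

    @property
    def duration(self) -> float:
        """Common recorded span (s), limited by the shortest stream."""
        return min(
            self.emg.shape[1] / self.rates["emg"],
            self.pressure.shape[1] / self.rates["pressure"],
            self.acc.shape[1] / self.rates["acc"],
            self.video.shape[0] / self.rates["video"],
        )


def _interp_rows(template: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Evaluate a (C, N_PHASE) template at arbitrary phases in [0, 1]."""
    out = np.empty((template.shape[0], phases.size))
    grid = arch._PHASE
    for c in range(template.shape[0]):
        out[c] = np.interp(phases, grid, template[c])
    return out


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Per-subject substream derived from the cohort seed by a fixed offset."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index,)))


def _add_segments(stream: np.ndarray, rate: float, sensor: str,
                  segs: list[tuple[str, float, float]], scale: float) -> None:
    for activity, t0, t1 in segs:
        d = t1 - t0
        i0 = int(np.ceil(t0 * rate))
        i1 = int(np.floor(t1 * rate))
        idx = np.arange(i0, min(i1 + 1, stream.shape[1]))
        phases = (idx / rate - t0) / d
        tmpl = activity_archetype(activity, sensor)
        stream[:, idx] += scale * _interp_rows(tmpl, phases)


def generate_recording(config: CohortConfig, subject_index: int
                       ) -> tuple[MultiSensorRecording, pd.DataFrame]:
    """Generate one subject's streams and labeled segments."""
    rng = _subject_rng(config.seed, subject_index)
    subject_id = f"S{subject_index + 1:02d}"

    # fixed draw order: amplitude scales, ACC offset jitter, repetition
    # counts, durations, presentation order, gaps, then per-sensor noise
    scales = {s: m for s, m in zip(
        SENSOR_KEYS, rng.lognormal(0.0, config.subject_scale_sd, 4))}
    acc_offset = ACC_BASELINE + rng.normal(0.0, 0.02, 3)
    lo, hi = config.reps_range
    reps = rng.integers(lo, hi + 1, size=len(config.activities))
    durations: list[np.ndarray] = []
    for a, act in enumerate(config.activities):
        med, sd = config.duration_model[act]
        durations.append(rng.lognormal(np.log(med), sd, reps[a]))
    rep_list = [(act, d) for a, act in enumerate(config.activities) for d in durations[a]]
    order = rng.permutation(len(rep_list))
    gaps = rng.uniform(*config.gap_range_s, size=len(rep_list))

    segs: list[tuple[str, float, float]] = []
    t = config.lead_in_s
    for j, k in enumerate(order):
        act, d = rep_list[k]
        segs.append((act, t, t + d))
        t += d + gaps[j]
    total = t + config.tail_s

    streams: dict[str, np.ndarray] = {}
    for sensor, n_ch in (("emg", 8), ("pressure", 64), ("acc", 3)):
        rate = getattr(config, f"{sensor}_rate")
        n = int(round(total * rate))
        stream = np.zeros((n_ch, n))
        if sensor == "pressure":
            stream += (PRESSURE_BASELINE * arch._SENSEL_GAIN)[:, None]
        elif sensor == "acc":
            stream += acc_offset[:, None]
        _add_segments(stream, rate, sensor, segs, scales[sensor])
        sd = config.noise[sensor]
        if sd > 0:
            stream += rng.normal(0.0, sd, stream.shape)
        streams[sensor] = stream

    video = _render_video(config, segs, total, scales["video"], rng)

    seg_df = pd.DataFrame(
        [(subject_id, act, t0, t1) for act, t0, t1 in segs],
        columns=["subject", "activity", "t_start", "t_end"],
    )
    rec = MultiSensorRecording(
        subject_id=subject_id,
        emg=streams["emg"], pressure=streams["pressure"], acc=streams["acc"],
        video=video,
        rates={"emg": config.emg_rate, "pressure": config.pressure_rate,
               "acc": config.acc_rate, "video": config.video_rate},
        lead_in_s=config.lead_in_s,
    )
    return rec, seg_df


def _render_video(config: CohortConfig, segs: list[tuple[str, float, float]],
                  total: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    shape = config.frame_shape
    fps = config.video_rate
    n_frames = int(round(total * fps))
    rest = _render_frame(shape, (0.0, 0.0))
    sd = config.noise["video"]
    frames = np.empty((n_frames,) + shape, dtype=np.uint8)

    seg_starts = np.array([t0 for _, t0, _ in segs])
    frame_t = np.arange(n_frames) / fps
    seg_of_frame = np.searchsorted(seg_starts, frame_t, side="right") - 1

    for f in range(n_frames):
        j = seg_of_frame[f]
        img = rest
        if j >= 0:
            act, t0, t1 = segs[j]
            if frame_t[f] < t1:
                p = (frame_t[f] - t0) / (t1 - t0)
                img = _render_frame(shape, activity_offset(act, p, shape, scale))
        if sd > 0:
            img = img + rng.normal(0.0, sd, shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return frames


def generate_cohort(config: CohortConfig
                    ) -> tuple[list[MultiSensorRecording], pd.DataFrame]:
    """Generate the full cohort: one recording per subject plus the
    labeled segment table (subject, activity, t_start, t_end; seconds)."""
    recordings: list[MultiSensorRecording] = []
    seg_tables: list[pd.DataFrame] = []
    for i in range(config.n_subjects):
        rec, seg = generate_recording(config, i)
        recordings.append(rec)
        seg_tables.append(seg)
    segments = pd.concat(seg_tables, ignore_index=True)
    return recordings, segments


def validate_segments(segments: pd.DataFrame) -> None:
    """Check the SegmentTable invariants; raise HarkitError on violation."""
    required = {"subject", "activity", "t_start", "t_end"}
    if not required.issubset(segments.columns):
        raise HarkitError(f"segment table must have columns {sorted(required)}")
    if not (segments["t_end"] > segments["t_start"]).all():
        raise HarkitError("every segment must satisfy t_end > t_start")
    bad = set(segments["activity"]) - set(ACTIVITIES)
    if bad:
        raise HarkitError(f"unknown activity labels in segment table: {sorted(bad)}")
    for subject, grp in segments.groupby("subject"):
        g = grp.sort_values("t_start")
        if (g["t_start"].to_numpy()[1:] < g["t_end"].to_numpy()[:-1]).any():
            raise HarkitError(f"overlapping segments for subject {subject}")
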