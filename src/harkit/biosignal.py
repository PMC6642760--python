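"""EMG, plantar-pressure and accelerometer feature chains.

Each chain turns a fixed-width multichannel clip into a classifier input
vector sampled at 25 Hz:

* EMG (sensor B): rectify -> 0.1 s moving average -> divide by the
  subject's global EMG maximum -> unit-interval normalize -> resample each
  channel to 25 Hz -> concatenate EL1..EL4, ER1..ER4.
* Pressure (sensor C): average the 64 sensels into six anatomical regions
  (heel/center/front per foot) -> 0.3 s moving average -> subject maximum
  -> unit-interval normalize -> 25 Hz -> concatenate L1 L2 L3 R1 R2 R3.
* Acceleration (sensor E): subtract the per-channel offset estimated from
  a >= 10 s stationary lead-in, take the deviation magnitude -> 0.2 s
  moving average -> subject maximum -> unit-interval normalize -> 25 Hz ->
  concatenate X, Y, Z.

Amplitude normalization is subject-specific: the divisor is the maximum of
the processed signal over all of that subject's measurements of all
activities, so multiplying a subject's raw stream by a constant leaves
their features unchanged.  The final unit-interval normalization is applied
before resampling (the chain's printed order); linear interpolation may
therefore leave the post-resample maximum marginally below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (DegenerateSubjectError, DegenerateVectorError,
                     HarkitError, LayoutError)
from .archetypes import default_pressure_layout

#: sensor codes of the emulated study: B = EMG, C = pressure, E = ACC
BIOSIGNAL_SENSORS = ("B", "C", "E")


@dataclass
class FeatureParams:
    """Tunable widths of the per-sensor chains (seconds / Hz)."""

    emg_smooth_s: float = 0.1
    pressure_smooth_s: float = 0.3
    acc_smooth_s: float = 0.2
    resample_rate: float = 25.0


@dataclass
class FeatureVector:
    """A fixed-length feature vector with its provenance."""

    values: np.ndarray
    sensor: str
    subject: str | None = None
    activity: str | None = None

    @property
    def dimension(self) -> int:
        return int(self.values.size)


@dataclass
class SubjectNormalizer:
    """Per-subject amplitude references: one positive maximum per sensor
    (over the subject's full processed recording) and the accelerometer
    offsets estimated from the stationary lead-in."""

    subject_id: str
    emg_max: float
    pressure_max: float
    acc_max: float
    acc_offsets: np.ndarray

    def __post_init__(self):
        for name in ("emg_max", "pressure_max", "acc_max"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DegenerateSubjectError(
                    f"{self.subject_id}: {name} must be finite and > 0, got {v}")
        if not np.all(np.isfinite(self.acc_offsets)):
            raise DegenerateSubjectError(f"{self.subject_id}: non-finite ACC offsets")


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(signal)


def moving_average(signal: np.ndarray, width_s: float, rate: float) -> np.ndarray:
    """Centered moving mean over ``round(width_s * rate)`` samples.

    The window shrinks to the available samples at the edges, so the output
    has the input's length and constant signals pass through unchanged.
    Operates along the last axis.
    """
    m = int(round(width_s * rate))
    if m < 1:
        raise HarkitError(
            f"moving-average width {width_s} s is shorter than one sample at {rate} Hz")
    n = signal.shape[-1]
    half_left = (m - 1) // 2
    half_right = m - 1 - half_left
    lo = np.clip(np.arange(n) - half_left, 0, n)
    hi = np.clip(np.arange(n) + half_right + 1, 0, n)
    csum = np.concatenate(
        [np.zeros(signal.shape[:-1] + (1,)), np.cumsum(signal, axis=-1)], axis=-1)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def subject_max_normalize(signal: np.ndarray, max_value: float) -> np.ndarray:
    """Divide by the subject's global per-sensor maximum."""
    if not np.isfinite(max_value) or max_value <= 0:
        raise DegenerateSubjectError(f"subject maximum must be > 0, got {max_value}")
    return signal / max_value


def unit_interval_normalize(vector: np.ndarray) -> np.ndarray:
    """Scale so the maximum is exactly 1; requires a strictly positive value."""
    m = float(np.max(vector))
    if not np.isfinite(m) or m <= 0:
        raise DegenerateVectorError(
            "cannot normalize to the unit interval: no strictly positive value")
    return vector / m


def resample_25hz(signal: np.ndarray, rate_in: float, rate_out: float = 25.0
                  ) -> np.ndarray:
    """Linear interpolation at the target timestamps k / rate_out.

    Output length is ``round(duration * rate_out)``; upsampling is not
    supported (the chains only ever reduce the rate).
    Operates along the last axis.
    """
    if rate_in < rate_out:
        raise HarkitError(f"cannot resample {rate_in} Hz up to {rate_out} Hz")
    n_in = signal.shape[-1]
    duration = n_in / rate_in
    n_out = int(round(duration * rate_out))
    t_out = np.arange(n_out) / rate_out
    t_in = np.arange(n_in) / rate_in
    flat = signal.reshape(-1, n_in)
    out = np.empty((flat.shape[0], n_out))
    for c in range(flat.shape[0]):
        out[c] = np.interp(t_out, t_in, flat[c])
    return out.reshape(signal.shape[:-1] + (n_out,))


def pressure_region_average(frame: np.ndarray, layout: np.ndarray | None = None
                            ) -> np.ndarray:
    """Mean sensel value of the six regions L1 L2 L3 R1 R2 R3.

    ``frame`` is (64,) or (64, n_samples); ``layout`` assigns every sensel
    to exactly one region index 0..5 (default: the synthetic 8x4-per-foot
    grid with rows 1-3 front, 4-5 center, 6-8 heel).
    """
    layout = default_pressure_layout() if layout is None else np.asarray(layout)
    if layout.shape != (64,):
        raise LayoutError(f"layout must assign all 64 sensels, got shape {layout.shape}")
    if frame.shape[0] != 64:
        raise HarkitError(f"expected 64 sensels, got {frame.shape[0]}")
    present = set(np.unique(layout).tolist())
    if not present <= set(range(6)):
        raise LayoutError(f"layout regions must be integers 0..5, got {sorted(present)}")
    if present != set(range(6)):
        raise LayoutError(f"empty region(s): {sorted(set(range(6)) - present)}")
    out = np.stack([frame[layout == r].mean(axis=0) for r in range(6)])
    return out


def acc_remove_offset(signal_xyz: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Per-channel subtraction of the stationary (gravity) offsets."""
    offsets = np.asarray(offsets, dtype=float)
    if signal_xyz.shape[0] != 3 or offsets.shape != (3,):
        raise HarkitError("expected a 3-channel signal and 3 offsets")
    return signal_xyz - offsets[:, None]


def compute_normalizer(recording, params: FeatureParams | None = None,
                       layout: np.ndarray | None = None) -> SubjectNormalizer:
    """Build a subject's amplitude references from their full recording.

    The maxima are taken on the processed representation each chain divides
    (rectified+smoothed EMG, region-averaged+smoothed pressure, smoothed
    acceleration-deviation magnitude), over all measurements of all
    activities.  ACC offsets are the per-channel means of the first 10 s of
    the stationary lead-in.
    """
    params = params or FeatureParams()
    if recording.lead_in_s < 10.0:
        raise HarkitError("accelerometer offset needs a >= 10 s stationary lead-in")
    r = recording.rates
    emg_env = moving_average(rectify(recording.emg), params.emg_smooth_s, r["emg"])
    press = pressure_region_average(recording.pressure, layout)
    press_env = moving_average(press, params.pressure_smooth_s, r["pressure"])
    n_off = int(round(10.0 * r["acc"]))
    offsets = recording.acc[:, :n_off].mean(axis=1)
    acc_dev = rectify(acc_remove_offset(recording.acc, offsets))
    acc_env = moving_average(acc_dev, params.acc_smooth_s, r["acc"])
    return SubjectNormalizer(
        subject_id=recording.subject_id,
        emg_max=float(emg_env.max()),
        pressure_max=float(press_env.max()),
        acc_max=float(acc_env.max()),
        acc_offsets=offsets,
    )


def build_biosignal_feature(clip: np.ndarray, rate: float, sensor: str,
                            normalizer: SubjectNormalizer,
                            params: FeatureParams | None = None,
                            layout: np.ndarray | None = None,
                            subject: str | None = None,
                            activity: str | None = None) -> FeatureVector:
    """Apply one sensor's full chain to a windowed clip.

    ``sensor`` is "B" (EMG, clip (8, n)), "C" (pressure, clip (64, n)) or
    "E" (acceleration, clip (3, n)); ``rate`` is the clip's sampling rate.
    The returned vector has dimension n_channels x round(duration * 25).
    """
    params = params or FeatureParams()
    if sensor == "B":
        x = rectify(clip)
        x = moving_average(x, params.emg_smooth_s, rate)
        x = subject_max_normalize(x, normalizer.emg_max)
    elif sensor == "C":
        x = pressure_region_average(clip, layout)
        x = moving_average(x, params.pressure_smooth_s, rate)
        x = subject_max_normalize(x, normalizer.pressure_max)
    elif sensor == "E":
        x = rectify(acc_remove_offset(clip, normalizer.acc_offsets))
        x = moving_average(x, params.acc_smooth_s, rate)
        x = subject_max_normalize(x, normalizer.acc_max)
    else:
        raise HarkitError(f"unknown biosignal sensor {sensor!r} (expected B, C or E)")
    x = unit_interval_normalize(x)
    x = resample_25hz(x, rate, params.resample_rate)
    return FeatureVector(values=x.reshape(-1), sensor=sensor,
                         subject=subject or normalizer.subject_id, activity=activity)
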