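"""Deterministic per-activity signal templates ("archetypes").

Each of the 12 elementary activities (squat down/up 1a/1b, sit/stand 2a/2b,
reach forward/return 3a/3b, reach up/return 4a/4b, trunk bend/straighten
5a/5b, right/left step 6a/6b) is encoded, per sensor, as a unit-duration
multichannel template built from smooth Gaussian bumps.  No biomechanical
model is claimed: the templates only encode the qualitative structure a
classifier must separate — which muscles fire when, which foot regions load
when, how the trunk accelerates, and in which direction the silhouette moves.

Conventions
-----------
* Templates are sampled on ``N_PHASE`` points of the unit interval (phase
  ``p in (0, 1)``); downstream code interpolates to the drawn duration.
* "b" variants of a movement are the time-reversed "a" dynamics with a
  slightly reduced amplitude (eccentric vs. concentric asymmetry), except
  the steps 6a/6b which are left/right mirrors.
* EMG channels: EL1..EL4, ER1..ER4 = (quadriceps, biceps femoris, tibialis
  anterior, gastrocnemius) of the left then right leg.
* Pressure: 64 sensels, 32 per foot on an 8-row x 4-column grid; region
  deviations (heel/center/front per foot) are spread over the grid with a
  fixed per-sensel gain pattern.
* ACC channels: X forward, Y lateral, Z vertical; templates are deviations
  from the stationary (gravity) baseline.
"""

from __future__ import annotations

import numpy as np

from .errors import UnknownActivityError

ACTIVITIES: tuple[str, ...] = (
    "1a", "1b", "2a", "2b", "3a", "3b", "4a", "4b", "5a", "5b", "6a", "6b",
)
EMG_CHANNELS: tuple[str, ...] = (
    "EL1", "EL2", "EL3", "EL4", "ER1", "ER2", "ER3", "ER4",
)
PRESSURE_REGIONS: tuple[str, ...] = ("L1", "L2", "L3", "R1", "R2", "R3")
ACC_CHANNELS: tuple[str, ...] = ("X", "Y", "Z")
SENSORS: tuple[str, ...] = ("emg", "pressure", "acc")

N_PHASE = 240
_PHASE = (np.arange(N_PHASE) + 0.5) / N_PHASE

# reversal amplitude factor for "b" variants (concentric/eccentric asymmetry)
_REV = 0.92


def _bump(center: float, width: float, amp: float = 1.0) -> np.ndarray:
    return amp * np.exp(-0.5 * ((_PHASE - center) / width) ** 2)


def _taper(edge: float = 0.08) -> np.ndarray:
    """Smoothstep envelope: every activity starts and ends at rest, so
    templates carry no discontinuity at the segment boundaries."""
    x = np.minimum(np.minimum(_PHASE / edge, (1.0 - _PHASE) / edge), 1.0)
    return x * x * (3.0 - 2.0 * x)


_TAPER = _taper()


# ---------------------------------------------------------------------------
# EMG: per movement family, (amp, center, width) for the four muscles
# (quadriceps, biceps femoris, tibialis anterior, gastrocnemius).
# ---------------------------------------------------------------------------
_EMG_A = {
    "1": [(1.00, 0.35, 0.16), (0.40, 0.55, 0.18), (0.50, 0.30, 0.14), (0.30, 0.70, 0.16)],
    "2": [(0.80, 0.30, 0.18), (0.60, 0.50, 0.16), (0.60, 0.22, 0.12), (0.20, 0.62, 0.18)],
    "3": [(0.20, 0.45, 0.20), (0.50, 0.40, 0.16), (0.70, 0.33, 0.14), (0.60, 0.58, 0.16)],
    "4": [(0.30, 0.42, 0.18), (0.30, 0.33, 0.14), (0.40, 0.52, 0.16), (0.90, 0.45, 0.14)],
    "5": [(0.15, 0.50, 0.22), (1.00, 0.40, 0.16), (0.30, 0.62, 0.16), (0.50, 0.34, 0.14)],
}
# step: leading leg fires early, trailing leg same pattern delayed and weaker
_EMG_STEP_LEAD = [(0.70, 0.25, 0.12), (0.40, 0.45, 0.14), (0.80, 0.20, 0.10), (0.80, 0.60, 0.14)]
_EMG_STEP_TRAIL = [(0.38, 0.53, 0.12), (0.22, 0.73, 0.14), (0.44, 0.48, 0.10), (0.44, 0.88, 0.14)]
# mild physiological left/right asymmetry for the bilateral movements
_EMG_LR = (1.0, 0.95)


def _emg_template(activity: str) -> np.ndarray:
    fam, variant = activity[0], activity[1]
    out = np.zeros((8, N_PHASE))
    if fam == "6":
        lead, trail = (_EMG_STEP_LEAD, _EMG_STEP_TRAIL)
        # 6a: right leg steps (leads); 6b mirrored
        sides = {"a": ("R", "L"), "b": ("L", "R")}[variant]
        for params, side in zip((lead, trail), sides):
            base = 4 if side == "R" else 0
            for m, (amp, c, w) in enumerate(params):
                out[base + m] = _bump(c, w, amp)
        return out * _TAPER
    for m, (amp, c, w) in enumerate(_EMG_A[fam]):
        out[m] = _bump(c, w, amp * _EMG_LR[0])
        out[4 + m] = _bump(c, w, amp * _EMG_LR[1])
    if variant == "b":
        out = out[:, ::-1] * _REV
    return np.ascontiguousarray(out * _TAPER)


# ---------------------------------------------------------------------------
# Pressure: region deviations, order (L1 heel, L2 center, L3 front, R1, R2, R3)
# as lists of (region, amp, center, width) bumps; negative amp = unloading.
# ---------------------------------------------------------------------------
_PRESSURE_A = {
    "1": [("L1", 0.55, 0.42, 0.20), ("R1", 0.55, 0.42, 0.20),
          ("L3", -0.15, 0.42, 0.20), ("R3", -0.15, 0.42, 0.20)],
    "2": [("L1", 0.30, 0.25, 0.14), ("R1", 0.30, 0.25, 0.14),
          ("L1", -0.35, 0.72, 0.16), ("R1", -0.35, 0.72, 0.16),
          ("L2", -0.30, 0.70, 0.18), ("R2", -0.30, 0.70, 0.18),
          ("L3", -0.30, 0.68, 0.18), ("R3", -0.30, 0.68, 0.18)],
    "3": [("L3", 0.35, 0.45, 0.16), ("R3", 0.35, 0.45, 0.16),
          ("L1", -0.25, 0.45, 0.18), ("R1", -0.25, 0.45, 0.18)],
    "4": [("L3", 0.50, 0.40, 0.14), ("R3", 0.50, 0.40, 0.14),
          ("L1", -0.30, 0.40, 0.16), ("R1", -0.30, 0.40, 0.16),
          ("L2", 0.15, 0.42, 0.18), ("R2", 0.15, 0.42, 0.18)],
    "5": [("L3", 0.30, 0.42, 0.20), ("R3", 0.30, 0.42, 0.20),
          ("L2", 0.40, 0.35, 0.16), ("R2", 0.40, 0.35, 0.16),
          ("L1", -0.35, 0.40, 0.18), ("R1", -0.35, 0.40, 0.18)],
}
# 6a: right heel strikes first, then left; forefeet roll through later
_PRESSURE_STEP = [("R1", 0.50, 0.25, 0.12), ("L1", 0.50, 0.55, 0.12),
                  ("R3", 0.40, 0.45, 0.14), ("L3", 0.30, 0.75, 0.14),
                  ("L1", -0.20, 0.30, 0.12), ("R2", 0.12, 0.35, 0.14),
                  ("L2", 0.12, 0.65, 0.14)]


def _mirror_region(region: str) -> str:
    return ("R" if region[0] == "L" else "L") + region[1]


def _pressure_region_template(activity: str) -> np.ndarray:
    """(6, N_PHASE) deviation of the region means from the standing load."""
    fam, variant = activity[0], activity[1]
    out = np.zeros((6, N_PHASE))
    if fam == "6":
        bumps = _PRESSURE_STEP
        if variant == "b":
            bumps = [(_mirror_region(r), a, c, w) for r, a, c, w in bumps]
        for region, amp, c, w in bumps:
            out[PRESSURE_REGIONS.index(region)] += _bump(c, w, amp)
        return out * _TAPER
    for region, amp, c, w in _PRESSURE_A[fam]:
        out[PRESSURE_REGIONS.index(region)] += _bump(c, w, amp)
    if variant == "b":
        out = out[:, ::-1] * _REV
    return np.ascontiguousarray(out * _TAPER)


# Fixed per-sensel gain pattern: sensels of one region do not load perfectly
# uniformly; the pattern is deterministic so archetypes stay reproducible.
_SENSEL_GAIN = 0.85 + 0.30 * ((np.arange(64) * 37) % 64) / 63.0


def default_pressure_layout() -> np.ndarray:
    """Region index (0..5 = L1,L2,L3,R1,R2,R3) of each of the 64 sensels.

    Per foot an 8-row x 4-column grid, row-major, left foot first:
    rows 1-3 front (region 3), rows 4-5 center (2), rows 6-8 heel (1).
    """
    layout = np.empty(64, dtype=np.int64)
    for s in range(64):
        foot = s // 32            # 0 left, 1 right
        row = (s % 32) // 4       # 0..7
        if row <= 2:
            region = 2            # front
        elif row <= 4:
            region = 1            # center
        else:
            region = 0            # heel
        layout[s] = 3 * foot + region
    return layout


_LAYOUT = default_pressure_layout()


def _pressure_template(activity: str) -> np.ndarray:
    regions = _pressure_region_template(activity)
    return _SENSEL_GAIN[:, None] * regions[_LAYOUT]


# ---------------------------------------------------------------------------
# ACC: (channel, amp, center, width) deviations from the gravity baseline.
# ---------------------------------------------------------------------------
_ACC_A = {
    "1": [("Z", -0.80, 0.40, 0.18), ("X", 0.30, 0.35, 0.16)],
    "2": [("Z", -0.60, 0.55, 0.20), ("X", -0.35, 0.50, 0.18), ("Y", 0.15, 0.45, 0.20)],
    "3": [("X", 0.60, 0.40, 0.16), ("Z", 0.15, 0.45, 0.20)],
    "4": [("Z", 0.55, 0.40, 0.16), ("X", 0.20, 0.55, 0.18)],
    "5": [("X", 0.70, 0.38, 0.18), ("Z", -0.35, 0.50, 0.18), ("Y", 0.10, 0.40, 0.20)],
}
# steps: a sternum sensor sees the forward rock mirrored in time between the
# leading legs and the lateral sway peaking at different phases; both stay
# distinct under the downstream deviation-magnitude transform
_ACC_STEP = {
    "a": [("X", 0.50, 0.30, 0.14), ("X", -0.40, 0.70, 0.14),
          ("Y", 0.45, 0.35, 0.14), ("Z", 0.25, 0.50, 0.28)],
    "b": [("X", -0.40, 0.30, 0.14), ("X", 0.50, 0.70, 0.14),
          ("Y", -0.45, 0.62, 0.14), ("Z", 0.25, 0.45, 0.18)],
}


def _acc_template(activity: str) -> np.ndarray:
    fam, variant = activity[0], activity[1]
    out = np.zeros((3, N_PHASE))
    if fam == "6":
        for ch, amp, c, w in _ACC_STEP[variant]:
            out[ACC_CHANNELS.index(ch)] += _bump(c, w, amp)
        return out * _TAPER
    for ch, amp, c, w in _ACC_A[fam]:
        out[ACC_CHANNELS.index(ch)] += _bump(c, w, amp)
    if variant == "b":
        out = out[:, ::-1] * _REV
    return np.ascontiguousarray(out * _TAPER)


def activity_archetype(activity: str, sensor: str) -> np.ndarray:
    """Unit-duration multichannel template of ``activity`` on ``sensor``.

    Parameters
    ----------
    activity : one of the 12 labels ``1a`` .. ``6b``.
    sensor : ``"emg"`` (8 x N_PHASE), ``"pressure"`` (64 x N_PHASE,
        deviation from the standing load) or ``"acc"`` (3 x N_PHASE,
        deviation from the gravity baseline).

    The result is deterministic, bounded, and pairwise distinct across
    activities on every sensor.
    """
    if activity not in ACTIVITIES:
        raise UnknownActivityError(f"unknown activity label {activity!r}")
    if sensor == "emg":
        return _emg_template(activity)
    if sensor == "pressure":
        return _pressure_template(activity)
    if sensor == "acc":
        return _acc_template(activity)
    raise ValueError(f"unknown sensor {sensor!r} (expected emg/pressure/acc)")


def video_motion(activity: str) -> dict:
    """Silhouette motion parameters for one activity.

    Each activity moves the textured body blob along a distinct display-space
    direction (counter-clockwise from the image +x axis) with a distinct
    number of back-and-forth pulses and excursion, so optical-flow direction
    histograms separate the classes.
    """
    if activity not in ACTIVITIES:
        raise UnknownActivityError(f"unknown activity label {activity!r}")
    k = ACTIVITIES.index(activity)
    return {
        "angle_deg": 30.0 * k,
        "n_pulses": 1 + (k % 3),
        "amplitude_frac": 0.16 + 0.01 * k,
    }
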