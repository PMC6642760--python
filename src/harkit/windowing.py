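"""Performance-time histograms and fixed-width window extraction.

Activity repetitions vary in duration between movements and subjects, so
classifier inputs are cut to a fixed window of ``W`` seconds (default
1.6 s).  The choice of W is supported by duration histograms: MIN/MAX/AVG
per (subject, activity), a pooled ALL histogram, and one histogram per
activity.  Windows are centered on the segment midpoint by default, so a
short repetition sits symmetrically inside its context; start-aligned
windows are available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import HarkitError, OutOfSpanError


@dataclass
class WindowSpec:
    """Fixed analysis window: width ``W`` seconds, anchored at the segment
    center (default) or start."""

    W: float = 1.6
    alignment: str = "center"

    def __post_init__(self):
        if self.W <= 0:
            raise HarkitError("window width W must be positive")
        if self.alignment not in ("center", "start"):
            raise HarkitError("alignment must be 'center' or 'start'")


@dataclass
class DurationHistogramSet:
    """Bin edges plus counts for MIN/MAX/AVG/ALL and each activity."""

    edges: np.ndarray
    min: np.ndarray
    max: np.ndarray
    avg: np.ndarray
    all: np.ndarray
    per_activity: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: activity (or MIN/MAX/AVG/ALL), bin_left,
        bin_right, count."""
        rows = []
        named = {"MIN": self.min, "MAX": self.max, "AVG": self.avg, "ALL": self.all}
        for name, counts in list(named.items()) + sorted(self.per_activity.items()):
            for left, right, c in zip(self.edges[:-1], self.edges[1:], counts):
                rows.append((name, left, right, int(c)))
        return pd.DataFrame(rows, columns=["activity", "bin_left", "bin_right", "count"])


def duration_histograms(segments: pd.DataFrame, bin_width: float = 0.1
                        ) -> DurationHistogramSet:
    """Histogram the repetition durations of a segment table.

    MIN/MAX/AVG hold one value per (subject, activity); ALL and the
    per-activity histograms hold one value per repetition.
    """
    if len(segments) == 0:
        raise HarkitError("segment table is empty")
    if bin_width <= 0:
        raise HarkitError("bin width must be positive")
    durations = (segments["t_end"] - segments["t_start"]).to_numpy(dtype=float)
    n_bins = int(np.ceil(durations.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width

    by_pair = segments.assign(duration=durations).groupby(["subject", "activity"])["duration"]
    hist = lambda x: np.histogram(x, bins=edges)[0]
    per_activity = {
        act: hist((grp["t_end"] - grp["t_start"]).to_numpy())
        for act, grp in segments.groupby("activity")
    }
    return DurationHistogramSet(
        edges=edges,
        min=hist(by_pair.min().to_numpy()),
        max=hist(by_pair.max().to_numpy()),
        avg=hist(by_pair.mean().to_numpy()),
        all=hist(durations),
        per_activity=per_activity,
    )


def window_sample_count(W: float, rate: float) -> int:
    """Samples (or frames) in a W-second window — depends only on W and rate."""
    return int(round(W * rate))


def extract_window(stream: np.ndarray, rate: float, t_start: float, t_end: float,
                   spec: WindowSpec | None = None, time_axis: int = -1) -> np.ndarray:
    """Cut a clip of exactly ``round(W * rate)`` samples around one segment.

    ``stream`` holds samples at ``rate`` Hz with sample ``i`` at time
    ``i / rate`` (seconds from recording start).  With center alignment the
    window is placed symmetrically about the segment midpoint; a window that
    does not fit inside the recorded span raises :class:`OutOfSpanError`.
    """
    spec = spec or WindowSpec()
    if t_end <= t_start:
        raise HarkitError("segment must satisfy t_end > t_start")
    n_out = window_sample_count(spec.W, rate)
    if spec.alignment == "center":
        window_start = 0.5 * (t_start + t_end) - spec.W / 2.0
    else:
        window_start = t_start
    i0 = int(round(window_start * rate))
    n_avail = stream.shape[time_axis]
    if i0 < 0 or i0 + n_out > n_avail:
        raise OutOfSpanError(
            f"window [{window_start:.3f}, {window_start + spec.W:.3f}] s "
            f"({n_out} samples from index {i0}) exceeds the recorded span "
            f"of {n_avail} samples at {rate} Hz")
    index = [slice(None)] * stream.ndim
    index[time_axis] = slice(i0, i0 + n_out)
    return np.ascontiguousarray(stream[tuple(index)])
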