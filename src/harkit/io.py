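"""Readers and writers for the artifact's on-disk formats.

Signal streams are delimited tables (first line a ``# rate_hz:`` field,
then a header row naming the channels, first column the time in seconds);
video frames are PGM files ``frame_%06d.pgm``; segment tables and feature
matrices are plain CSV.
"""

from __future__ import annotations

import glob
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .archetypes import ACC_CHANNELS, EMG_CHANNELS
from .classify import LabeledDataset
from .errors import HarkitError, LayoutError

PRESSURE_CHANNELS = tuple(f"P{j + 1:02d}" for j in range(64))
_CHANNELS = {"emg": EMG_CHANNELS, "pressure": PRESSURE_CHANNELS, "acc": ACC_CHANNELS}


def write_signal(path: str, stream: np.ndarray, rate: float, sensor: str) -> None:
    """Write one sensor stream as a delimited table with a rate field."""
    channels = _CHANNELS[sensor]
    if stream.shape[0] != len(channels):
        raise HarkitError(f"{sensor} stream must have {len(channels)} channels")
    t = np.arange(stream.shape[1]) / rate
    df = pd.DataFrame(stream.T, columns=list(channels))
    df.insert(0, "time_s", t)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz: {rate}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_signal(path: str) -> tuple[np.ndarray, float, list[str]]:
    """Read a stream written by :func:`write_signal`.

    Returns (channels x samples array, rate, channel names)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# rate_hz:"):
            raise HarkitError(f"{path}: missing '# rate_hz:' field")
        rate = float(first.split(":", 1)[1])
        df = pd.read_csv(fh)
    channels = [c for c in df.columns if c != "time_s"]
    return df[channels].to_numpy().T, rate, channels


def write_frames(directory: str, frames: np.ndarray) -> None:
    """Write video frames as ``frame_%06d.pgm``."""
    os.makedirs(directory, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(os.path.join(directory, f"frame_{i:06d}.pgm"),
                    np.asarray(frame, dtype=np.uint8))


def read_frames(directory: str) -> np.ndarray:
    """Read an ordered PGM/PNG frame directory into (n, H, W)."""
    paths = sorted(glob.glob(os.path.join(directory, "frame_*.p[gn][mg]")))
    if not paths:
        raise HarkitError(f"no frame_*.pgm / frame_*.png files in {directory}")
    return np.stack([iio.imread(p) for p in paths])


def write_segments(path: str, segments: pd.DataFrame) -> None:
    segments.to_csv(path, index=False,
                    columns=["subject", "activity", "t_start", "t_end"])


def read_segments(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject": str, "activity": str})


def write_features(path: str, dataset: LabeledDataset) -> None:
    """Feature matrix CSV: subject, activity, sensor, f_000...f_NNN."""
    d = dataset.X.shape[1]
    df = pd.DataFrame(dataset.X, columns=[f"f_{j:03d}" for j in range(d)])
    df.insert(0, "sensor", dataset.sensor)
    df.insert(0, "activity", dataset.y)
    df.insert(0, "subject", dataset.subjects)
    df.to_csv(path, index=False, float_format="%.10g")


def read_features(path: str) -> LabeledDataset:
    df = pd.read_csv(path, dtype={"subject": str, "activity": str, "sensor": str})
    feat_cols = [c for c in df.columns if c.startswith("f_")]
    sensors = df["sensor"].unique()
    if len(sensors) != 1:
        raise HarkitError(f"feature file mixes sensors: {sensors}")
    return LabeledDataset(df[feat_cols].to_numpy(), df["activity"].to_numpy(),
                          df["subject"].to_numpy(), sensor=sensors[0])


def read_layout(path: str) -> np.ndarray:
    """Pressure sensel-to-region layout from YAML (list of 64 region
    indices 0..5, or a mapping with key ``layout``)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = data.get("layout")
    layout = np.asarray(data)
    if layout.shape != (64,):
        raise LayoutError(f"{path}: layout must list 64 region indices")
    return layout.astype(np.int64)
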