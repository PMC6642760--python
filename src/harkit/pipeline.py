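"""End-to-end drivers: cohort -> features -> classification -> report.

This module wires the stages together so analyses, tests and the
acceptance script run one call.  Sensor codes follow the emulated study:
B = EMG, C = plantar pressure, D = video, E = accelerometer.  The split is
computed once on the segment labels and applied identically to every
sensor, so per-sensor results are comparable repetition by repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biosignal import (FeatureParams, build_biosignal_feature,
                        compute_normalizer)
from .classify import (LabeledDataset, SplitSpec, knn_predict, loo_select_k,
                       split_train_test)
from .cohort import CohortConfig, MultiSensorRecording, generate_cohort
from .errors import HarkitError
from .evaluate import RecognitionReport, build_confusion, build_report
from .optflow import FlowParams, build_video_feature
from .windowing import WindowSpec, extract_window

ALL_SENSORS = ("B", "C", "D", "E")
_SENSOR_STREAM = {"B": "emg", "C": "pressure", "E": "acc"}


@dataclass
class PipelineParams:
    """Everything downstream of the raw streams.

    ``n_train=None`` uses a third of the repetitions for learning (the
    emulated study's 2400 of 7274).  ``k="auto"`` selects k by leave-one-
    out on the learning set; an integer pins it.  The flow threshold
    default (0.3 px/frame) sits below the synthetic silhouette speeds.
    """

    window: WindowSpec = field(default_factory=WindowSpec)
    features: FeatureParams = field(default_factory=FeatureParams)
    flow: FlowParams = field(default_factory=lambda: FlowParams(T=0.3))
    sensors: tuple[str, ...] = ALL_SENSORS
    layout: np.ndarray | None = None
    n_train: int | None = None
    k: int | str = "auto"
    k_candidates: tuple[int, ...] = (1, 3, 5)
    split_seed: int = 0
    stratify: bool = True


@dataclass
class PipelineResult:
    datasets: dict[str, LabeledDataset]
    train_index: np.ndarray
    predictions: pd.DataFrame
    reports: dict[str, RecognitionReport]
    confusions: dict[str, pd.DataFrame]
    selected_k: dict[str, int]
    loo_accuracy: dict[str, dict[int, float]]

    def accuracy(self, sensor: str) -> float:
        """Overall test-set recognition rate R_s_a_ALL (percent)."""
        return self.reports[sensor].overall["R_ALL"]


def extract_features(recordings: list[MultiSensorRecording],
                     segments: pd.DataFrame,
                     params: PipelineParams | None = None
                     ) -> dict[str, LabeledDataset]:
    """Per-sensor feature matrices for every segment, rows aligned with
    the segment table."""
    params = params or PipelineParams()
    by_subject = {rec.subject_id: rec for rec in recordings}
    rows: dict[str, list[np.ndarray]] = {s: [] for s in params.sensors}
    labels, subjects = [], []
    for rec in recordings:
        seg = segments[segments["subject"] == rec.subject_id]
        norm = compute_normalizer(rec, params.features, params.layout)
        for _, row in seg.iterrows():
            t0, t1 = float(row["t_start"]), float(row["t_end"])
            for sensor in params.sensors:
                if sensor == "D":
                    clip = extract_window(rec.video, rec.rates["video"], t0, t1,
                                          params.window, time_axis=0)
                    vec = build_video_feature(clip, params.flow)
                else:
                    stream = getattr(rec, _SENSOR_STREAM[sensor])
                    rate = rec.rates[_SENSOR_STREAM[sensor]]
                    clip = extract_window(stream, rate, t0, t1, params.window)
                    vec = build_biosignal_feature(
                        clip, rate, sensor, norm, params.features,
                        params.layout, activity=row["activity"]).values
                rows[sensor].append(vec)
            labels.append(row["activity"])
            subjects.append(rec.subject_id)
    missing = set(segments["subject"]) - set(by_subject)
    if missing:
        raise HarkitError(f"segments reference unknown subjects: {sorted(missing)}")
    return {
        s: LabeledDataset(np.vstack(rows[s]), np.array(labels),
                          np.array(subjects), sensor=s)
        for s in params.sensors
    }


def classify_and_evaluate(datasets: dict[str, LabeledDataset],
                          params: PipelineParams | None = None) -> PipelineResult:
    """Split once, select k, predict the test set and build all reports."""
    params = params or PipelineParams()
    any_ds = next(iter(datasets.values()))
    n = len(any_ds)
    n_train = params.n_train if params.n_train is not None else max(n // 3, 12)
    spec = SplitSpec(n_train=n_train, seed=params.split_seed, stratify=params.stratify)
    # the split is index-based and shared by construction across sensors
    _, _, train_idx = split_train_test(any_ds, spec)
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    test_idx = np.flatnonzero(~mask)

    pred_frames = []
    reports, confusions, selected_k, loo_acc = {}, {}, {}, {}
    for sensor, ds in datasets.items():
        train, test = ds.take(train_idx), ds.take(test_idx)
        if params.k == "auto":
            k, acc = loo_select_k(train, params.k_candidates)
        else:
            k, acc = int(params.k), {}
        selected_k[sensor] = k
        loo_acc[sensor] = acc
        y_pred = knn_predict(train, test.X, k)
        pred_frames.append(pd.DataFrame({
            "segment_index": test_idx,
            "subject": test.subjects,
            "activity_true": test.y,
            "activity_pred": y_pred,
            "sensor": sensor,
        }))
        df = pred_frames[-1]
        reports[sensor] = build_report(df, sensor)
        confusions[sensor] = build_confusion(df)
    return PipelineResult(
        datasets=datasets, train_index=train_idx,
        predictions=pd.concat(pred_frames, ignore_index=True),
        reports=reports, confusions=confusions,
        selected_k=selected_k, loo_accuracy=loo_acc,
    )


def run_pipeline(config: CohortConfig, params: PipelineParams | None = None
                 ) -> PipelineResult:
    """Simulate a cohort and run the complete recognition analysis."""
    params = params or PipelineParams()
    recordings, segments = generate_cohort(config)
    datasets = extract_features(recordings, segments, params)
    return classify_and_evaluate(datasets, params)
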