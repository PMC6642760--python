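"""Shared desk-scale study conditions for the numbered analysis scripts.

All five stages operate on the same simulated cohort (fixed seed) so each
script can be re-run independently; intermediate arrays live under
scratch/, publishable tables under results/.
"""

from __future__ import annotations

import os

import numpy as np

from harkit import (CohortConfig, FlowParams, MultiSensorRecording,
                    PipelineParams)

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SCRATCH = os.path.join(ROOT, "scratch")
RESULTS = os.path.join(ROOT, "results")
COHORT_NPZ = os.path.join(SCRATCH, "cohort.npz")
SEGMENTS_CSV = os.path.join(RESULTS, "segments.csv")

#: 4 subjects x 12 activities x 5-8 repetitions at 90x72 video: the same
#: statistical structure as the full study, desk-sized.
DESK_CONFIG = CohortConfig(n_subjects=4, reps_range=(5, 8),
                           video_size=(90, 72), seed=7)

DESK_PARAMS = PipelineParams(flow=FlowParams(T=0.3, n_iter=60),
                             k="auto", k_candidates=(1, 3, 5), split_seed=8)

SENSOR_NAMES = {"B": "EMG", "C": "pressure", "D": "video", "E": "acceleration"}


def save_cohort(path: str, recordings: list[MultiSensorRecording]) -> None:
    arrays = {}
    for rec in recordings:
        sid = rec.subject_id
        arrays[f"{sid}_emg"] = rec.emg
        arrays[f"{sid}_pressure"] = rec.pressure
        arrays[f"{sid}_acc"] = rec.acc
        arrays[f"{sid}_video"] = rec.video
    arrays["subjects"] = np.array([r.subject_id for r in recordings])
    arrays["rates"] = np.array([recordings[0].rates[k]
                                for k in ("emg", "pressure", "acc", "video")])
    arrays["lead_in_s"] = np.array([recordings[0].lead_in_s])
    np.savez_compressed(path, **arrays)


def load_cohort(path: str) -> list[MultiSensorRecording]:
    with np.load(path, allow_pickle=False) as z:
        rates = dict(zip(("emg", "pressure", "acc", "video"), z["rates"]))
        lead = float(z["lead_in_s"][0])
        return [MultiSensorRecording(
            subject_id=str(sid),
            emg=z[f"{sid}_emg"], pressure=z[f"{sid}_pressure"],
            acc=z[f"{sid}_acc"], video=z[f"{sid}_video"],
            rates=rates, lead_in_s=lead)
            for sid in z["subjects"]]
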