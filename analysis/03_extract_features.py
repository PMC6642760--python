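"""Stage 3 — sensor-specific feature extraction.

Cuts a centered 1.6 s window from every labeled repetition and runs the
four chains: EMG envelope (rectify, 0.1 s smoothing, subject-max and unit
normalization, 25 Hz), pressure region averages (heel/center/front per
foot, 0.3 s smoothing), acceleration deviation magnitude (offset removal,
0.2 s smoothing), and the optical-flow direction histograms of the
silhouette contour.  One feature CSV per sensor goes to scratch/.
"""

import os
import time

from harkit import extract_features
from harkit.io import read_segments, write_features

from _common import (COHORT_NPZ, DESK_PARAMS, SCRATCH, SEGMENTS_CSV,
                     SENSOR_NAMES, load_cohort)


def main():
    recordings = load_cohort(COHORT_NPZ)
    segments = read_segments(SEGMENTS_CSV)
    t0 = time.time()
    datasets = extract_features(recordings, segments, DESK_PARAMS)
    for sensor, ds in datasets.items():
        path = os.path.join(SCRATCH, f"features_{sensor}.csv")
        write_features(path, ds)
        print(f"sensor {sensor} ({SENSOR_NAMES[sensor]}): "
              f"{ds.X.shape[0]} vectors x {ds.X.shape[1]} dims -> {path}")
    print(f"feature extraction took {time.time() - t0:.0f} s")


if __name__ == "__main__":
    main()
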