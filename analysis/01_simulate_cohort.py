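"""Stage 1 — simulate the multi-sensor cohort.

Generates the desk-scale synthetic cohort (4 subjects, 12 activities,
5-8 repetitions each; 8-channel EMG at 2 kHz, 64-sensel pressure and
triaxial acceleration at 100 Hz, 90x72 silhouette video at 25 fps) and
writes the labeled segment table to results/ and the raw streams to
scratch/.
"""

import os

from harkit import generate_cohort
from harkit.io import write_segments

from _common import COHORT_NPZ, DESK_CONFIG, RESULTS, SCRATCH, SEGMENTS_CSV, save_cohort


def main():
    os.makedirs(SCRATCH, exist_ok=True)
    os.makedirs(RESULTS, exist_ok=True)
    recordings, segments = generate_cohort(DESK_CONFIG)
    save_cohort(COHORT_NPZ, recordings)
    write_segments(SEGMENTS_CSV, segments)

    durs = segments["t_end"] - segments["t_start"]
    print(f"simulated {len(recordings)} subjects, {len(segments)} repetitions "
          f"of {segments['activity'].nunique()} activities")
    print(f"repetition durations: median {durs.median():.2f} s, "
          f"range {durs.min():.2f}-{durs.max():.2f} s")
    per_subject = segments.groupby('subject').size()
    print("repetitions per subject:", dict(per_subject))
    print(f"raw streams -> {COHORT_NPZ}")
    print(f"segment table -> {SEGMENTS_CSV}")


if __name__ == "__main__":
    main()
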