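"""Stage 5 — recognition reports and confusion matrices.

Builds, per sensor: the per-activity recognition rates R with their
inter-subject dispersions U, the column-normalized confusion matrix, and
the per-subject rates, mirroring the study's report tables (activities x
sensors; error matrices; subjects x sensors).
"""

import os

import pandas as pd

from harkit import (build_confusion, build_report, table_activities,
                    table_subjects)

from _common import RESULTS, SENSOR_NAMES


def main():
    preds = pd.read_csv(os.path.join(RESULTS, "predictions.csv"), dtype=str)
    reports = {}
    for sensor, df in preds.groupby("sensor"):
        reports[sensor] = build_report(df, sensor)
        cm = build_confusion(df)
        cm.round(1).to_csv(os.path.join(RESULTS, f"confusion_{sensor}.csv"))

    t1 = table_activities(reports)
    t6 = table_subjects(reports)
    t1.to_csv(os.path.join(RESULTS, "table1.csv"))
    t6.to_csv(os.path.join(RESULTS, "table6.csv"))

    print("per-activity recognition (R over U, percent):")
    print(t1.to_string())
    print()
    for sensor, rep in sorted(reports.items()):
        o = rep.overall
        print(f"sensor {sensor} ({SENSOR_NAMES[sensor]}): "
              f"R_ALL={o['R_ALL']:.1f}%  U_ALL={o['U_ALL']:.1f}  "
              f"U_V_ALL={o['U_V_ALL']:.1f}")
    print(f"\ntables -> {RESULTS}/table1.csv, confusion_<sensor>.csv, table6.csv")


if __name__ == "__main__":
    main()
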