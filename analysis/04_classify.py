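"""Stage 4 — k-NN classification of held-out repetitions.

Splits the repetitions once (stratified by activity, a third for
learning), selects k by leave-one-out on the learning set per sensor
(k = 1 wins throughout), and predicts the test repetitions under the
Manhattan metric.  Predictions for all four sensors go to results/.
"""

import os

from harkit import classify_and_evaluate
from harkit.io import read_features

from _common import DESK_PARAMS, RESULTS, SCRATCH, SENSOR_NAMES


def main():
    datasets = {s: read_features(os.path.join(SCRATCH, f"features_{s}.csv"))
                for s in SENSOR_NAMES}
    result = classify_and_evaluate(datasets, DESK_PARAMS)
    out = os.path.join(RESULTS, "predictions.csv")
    result.predictions.to_csv(out, index=False)
    n_train = len(result.train_index)
    n_test = len(result.predictions) // len(datasets)
    print(f"learning set {n_train} repetitions, test set {n_test}")
    for sensor in sorted(datasets):
        acc = result.loo_accuracy[sensor]
        print(f"sensor {sensor} ({SENSOR_NAMES[sensor]}): LOO " +
              ", ".join(f"k={k}: {100 * a:.1f}%" for k, a in sorted(acc.items()))
              + f" -> k={result.selected_k[sensor]}; "
              f"test accuracy {result.accuracy(sensor):.1f}%")
    print(f"predictions -> {out}")


if __name__ == "__main__":
    main()
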