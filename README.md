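# harkit — multi-sensor human activity recognition

Which motion sensor should a home-monitoring system use? `harkit`
implements, end to end, a comparison of four simultaneously recorded
modalities — surface EMG (sensor **B**), plantar pressure insoles
(**C**), silhouette video (**D**) and a sternum accelerometer (**E**) —
at the task of recognizing 12 elementary activities (squat down/up
`1a/1b`, sit/stand `2a/2b`, reach forward/return `3a/3b`, reach
up/return `4a/4b`, trunk bend/straighten `5a/5b`, right/left step
`6a/6b`). It is written for biomedical-signal and HAR researchers who
want the complete pipeline — simulation, feature chains, classification,
evaluation statistics — as tested, reusable code.

Because recordings of this kind cannot be redistributed, the package
includes a first-class synthetic cohort generator with the study's
statistical structure (20 subjects, ~30 repetitions per activity,
8-channel EMG at 2 kHz, 64 pressure sensels and triaxial acceleration at
100 Hz, 25 fps grayscale video), so every stage runs and is verified
without any external data.

## The method

Every labeled repetition is cut to a fixed window of W = 1.6 s (centered
on the repetition; W is justified by duration histograms) and reduced to
a per-sensor feature vector at 25 Hz:

* **EMG**: rectify → 0.1 s moving average → divide by the subject's
  global maximum → normalize to (0 1] → resample to 25 Hz → concatenate
  the 8 muscles (320 dims).
* **Pressure**: average sensels into heel/center/front regions per foot →
  0.3 s moving average → subject and unit normalization → 25 Hz →
  concatenate L1…R3 (240 dims).
* **Acceleration**: subtract the stationary offset (mean of a 10 s
  upright lead-in) → deviation magnitude → 0.2 s moving average →
  normalize → 25 Hz → concatenate X, Y, Z (120 dims).
* **Video**: per frame pair, Horn–Schunck optical flow; 5×5 median
  filtering; binarize the flow magnitude at a threshold T; form the
  moving-silhouette mask from the two neighbouring flow fields, fill
  holes, thicken the contour ~4 px inward; accumulate a normalized
  8-direction histogram of the flow over that contour band
  (38 frames × 8 bins = 304 dims).

Repetitions are split once (stratified, a third for learning) and
classified with k-NN under the Manhattan metric, k chosen by
leave-one-out on the learning set (k = 1 in practice). Results are
summarized per sensor s by the recognition correctness and its weighted
dispersion: for activity a,

    R_s_a = 100 · P_s_a / W_s_a,
    U_s_a = sqrt( Σᵢ wᵢ (xᵢ − R_s_a)² / ( ((n−1)/n) Σᵢ wᵢ ) ),

where P/W count correctly identified / all repetitions, xᵢ is subject
i's rate and wᵢ their repetition count; analogous statistics pool over
activities per subject (R_s_V, U_s_V) and overall (R_s_a_ALL, with
inter-subject U_s_a_ALL and inter-activity U_s_V_ALL). Confusion
matrices are column-normalized percentages with R_s_a on the diagonal.
See `docs/methods.md` for assumptions, parameter choices and
limitations.

## Worked example

The numbered scripts under `analysis/` run the study on a desk-scale
cohort (4 subjects, 5–8 repetitions per activity, 90×72 video, seed 7)
and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py     # streams + segment table
python analysis/02_duration_histograms.py # MIN/MAX/AVG/ALL histograms
python analysis/03_extract_features.py    # 4 feature matrices
python analysis/04_classify.py            # split, LOO k, predictions
python analysis/05_evaluate.py            # R/U tables, confusions
```

Stage 4 prints (this run: 296 repetitions, 98 learning / 198 test):

```
sensor B (EMG): LOO k=1: 100.0%, k=3: 100.0%, k=5: 100.0% -> k=1; test accuracy 100.0%
sensor C (pressure): LOO k=1: 100.0%, k=3: 95.9%, k=5: 92.9% -> k=1; test accuracy 97.5%
sensor D (video): LOO k=1: 100.0%, k=3: 99.0%, k=5: 99.0% -> k=1; test accuracy 100.0%
sensor E (acceleration): LOO k=1: 100.0%, k=3: 99.0%, k=5: 99.0% -> k=1; test accuracy 99.5%
```

and stage 5 summarizes each sensor's overall recognition rate with its
inter-subject and inter-activity dispersions:

```
sensor B (EMG): R_ALL=100.0%  U_ALL=0.0  U_V_ALL=0.0
sensor C (pressure): R_ALL=97.5%  U_ALL=5.2  U_V_ALL=9.2
sensor D (video): R_ALL=100.0%  U_ALL=0.0  U_V_ALL=0.0
sensor E (acceleration): R_ALL=99.5%  U_ALL=1.1  U_V_ALL=1.8
```

Under the generator's default noise the EMG and video chains recognize
every held-out repetition, while pressure and acceleration lose a few
percent — almost entirely on the reach-return `4b` (66.7% for pressure,
93.3% for acceleration in `results/table1.csv`), the movement with the
least distinctive loading pattern. The accompanying dispersion shows
those errors are subject-concentrated, the pattern the U statistics
exist to expose.

A `harkit` CLI offers the same stages for external data
(`harkit simulate|histogram|classify|evaluate --help`).

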