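# Methods

harkit reproduces, end to end, a multi-sensor human-activity-recognition
analysis: four synchronized modalities observe 12 elementary movements,
each modality is reduced to a fixed-length feature vector per repetition,
repetitions are classified with a nearest-neighbour rule, and recognition
quality is summarized by pooled rates and weighted dispersions. Because
the recordings such a study rests on are not redistributable, the package
ships a synthetic cohort generator with the same statistical structure,
so every downstream stage is testable without any download.

## The simulated cohort

`CohortConfig` defaults encode the emulated study: 20 subjects, 12
activity classes (squat down/up `1a/1b`, sit/stand `2a/2b`, reach
forward/return `3a/3b`, reach up/return `4a/4b`, trunk bend/straighten
`5a/5b`, right/left step `6a/6b`), 19–46 repetitions per (subject,
activity) drawn uniformly; 8-channel surface EMG at 2 kHz, 64-sensel
plantar pressure (32 per foot) at 100 Hz, triaxial sternum acceleration
at 100 Hz, grayscale silhouette video at 25 fps. Each recording opens
with a ≥ 10 s stationary lead-in (default 12 s) from which the
accelerometer offsets are later estimated.

Repetition durations are log-normal per activity with medians 1.3–2.1 s
and log-sd ≈ 0.16, chosen so the pooled duration histogram peaks below
2 s and the 1.6 s analysis window covers the bulk of repetitions — the
regime in which fixing W = 1.6 s is the sensible choice. Repetitions are
laid out in shuffled order with 0.8–1.2 s standing gaps.

Each repetition is an activity **archetype**: a deterministic,
unit-duration, multichannel template of smooth Gaussian bumps (muscle
bursts, foot-region loadings, trunk-acceleration deviations), multiplied
by a smoothstep taper so every activity starts and ends at rest, scaled
by a per-subject log-normal amplitude multiplier (`subject_scale_sd`,
default 0.15), time-warped to the drawn duration, and buried in additive
Gaussian noise (`noise_sd`; defaults 0.05 for EMG, 0.03 for pressure and
acceleration in archetype amplitude units, 2.0 intensity levels for
video). `b` variants are the time-reversed `a` dynamics at 0.92
amplitude (eccentric/concentric asymmetry); the steps `6a/6b` are
left/right mirrors with the leading heel striking first. No
biomechanical fidelity is claimed — the templates encode only the
qualitative structure a classifier must separate, and their pairwise
distinctness on every sensor is what the tests rely on.

Video frames are rendered analytically: a textured blob (sinusoid
texture, logistic edges) over a static textured background, translating
along an activity-specific display-space direction (multiples of 30°)
with 1–3 back-and-forth pulses and a bounded excursion that returns to
rest. Analytic rendering gives exact sub-pixel motion, which is what
optical-flow estimation needs; peak speeds are ≈ 1–4 px/frame at the
default desk-scale frame sizes.

Randomness is organized as one `SeedSequence` per cohort with per-subject
spawn keys and a fixed draw order, so equal seeds give byte-identical
cohorts and subjects are independent substreams.

What the generator deliberately does **not** emulate: real sEMG spectra
(only rectified-envelope structure), sensor drift and artifacts, marker
trajectories of the motion-capture reference (ground-truth segment times
are emitted directly), camera perspective or illumination changes, and
within-repetition style variability beyond amplitude and duration.
Passing tests therefore demonstrate that the processing chains and
statistics are implemented correctly and that the pipeline separates
classes whose structure matches its assumptions — not field performance
on real recordings.

## Windowing

Repetition durations vary, so classifier inputs are cut to W seconds
(default 1.6 s), `round(W · rate)` samples regardless of duration. The
window is **centered** on the segment midpoint: short repetitions sit
symmetrically inside standing context, long ones contribute their
central part. (Start-aligned windows are available; the anchor is a
package choice, as only the window's existence and width are given.)
Duration histograms (MIN/MAX/AVG per subject–activity, pooled ALL, and
per-activity; 0.1 s bins) are computed to justify W rather than to
automate it.

## Feature chains

* **EMG (sensor B)**: rectify → 0.1 s centered moving average → divide by
  the subject's global EMG maximum → unit-interval normalize → linear
  resample to 25 Hz → concatenate EL1..EL4, ER1..ER4 → 8 × 40 = 320 dims.
* **Pressure (C)**: average sensels into heel/center/front per foot
  (L1 L2 L3 R1 R2 R3) → 0.3 s moving average → subject maximum →
  unit normalize → 25 Hz → 6 × 40 = 240 dims.
* **Acceleration (E)**: subtract per-channel offsets (mean of the 10 s
  stationary lead-in) → take the deviation magnitude → 0.2 s moving
  average → subject maximum → unit normalize → 25 Hz → 3 × 40 = 120 dims.
* **Video (D)**: per interior frame, Horn–Schunck flow against both
  neighbours (Jacobi updates, zero init; α = 1, 100 iterations by
  default), 5 × 5 median filtering of u and v, magnitude binarization at
  a global threshold T, moving-silhouette mask as the union of the two
  binarized fields with holes filled, ≈ 4 px inner contour band
  (mask minus its erosion), and a magnitude-weighted, normalized 8 × 45°
  direction histogram over the band; concatenated over the (N−2) interior
  frames of an N-frame clip → 38 × 8 = 304 dims for W = 1.6 s.

Numerical choices worth knowing:

* **Moving averages** shrink their window at clip edges, preserving
  length and constants. **Resampling** is linear interpolation at k/25 s
  — the preceding moving averages already smooth, so no anti-alias
  filter is applied.
* **Normalization order**: unit-interval normalization precedes
  resampling (the chain's canonical order); interpolation can leave the
  post-resample maximum marginally below 1 and no renormalization is
  applied. "(0 1]" is realized as [0, 1]: exact zeros occur naturally
  (silent EMG, motionless frames) and excluding them would need an
  arbitrary epsilon.
* **Subject maxima** are taken on the processed representation each chain
  divides (e.g. the rectified, smoothed EMG), over the subject's full
  recording — so scaling a subject's raw stream by any constant leaves
  their features unchanged. The same global-maximum rule is used for all
  three biosignal chains.
* **Acceleration magnitude**: offset-removed acceleration is signed; the
  chain takes |deviation from rest| before smoothing so the feature
  respects the (0 1] amplitude contract. The cost is losing deviation
  sign, which the archetypes compensate with timing structure.
* **Pressure layout** is configuration (YAML), since no sensel map is
  universal; the synthetic default is an 8-row × 4-column grid per foot,
  rows 1–3 front, 4–5 center, 6–8 heel.
* **Flow angle convention**: image x rightward, y downward; angles CCW
  from +x in display space, bin B1 centered on 0° with 45° bins CCW
  (wrap-around B1 = [337.5°, 360°) ∪ [0°, 22.5°)). Magnitude-exactly-T
  pixels are *not* moving (strict inequality). The "joint part" of the
  two flow masks is the union by default (intersection by config); bins
  are magnitude-weighted (count weighting by config) since vectors, not
  pixels, are aggregated.
* **Horn–Schunck** α and iteration count are classical defaults (1.0,
  100), configurable; T defaults to 0.5 px/frame and is a config
  constant shared by all subjects. For the synthetic cohorts the
  pipeline uses T = 0.3, below the rendered silhouette speeds. The
  numba kernel and the pure-numpy reference implement the identical
  update and are cross-checked in tests.
* A clip whose histograms are all zero (no detected motion anywhere)
  surfaces a `DegenerateVectorError` rather than fabricating a vector.

## Classification and evaluation

Per-sensor `LabeledDataset`s share one stratified split (largest-
remainder proportional allocation; a third of repetitions for learning
by default, echoing a 2400-of-7274 split). k is selected by leave-one-out
accuracy on the learning set among {1, 3, 5}; k = 1 wins on these data.
Distances are Manhattan; ties are deterministic: equal distances prefer
the lower training-row index, tied votes go to the tied class owning the
nearest member.

Evaluation statistics: pooled rates R = 100·P/W per activity, per
subject, and overall; dispersions U are weighted standard deviations of
group rates around the **pooled** rate (not the weighted mean — the two
differ under unequal weights; the pooled-center form is the one
implemented throughout), with weights the group repetition counts and n
the number of positive-weight groups (zero-weight groups are excluded
rather than contributing undefined terms). With equal weights and a mean
center the statistic reduces to the classical sample SD, which the tests
verify. Confusion matrices are column-normalized percentages, so columns
sum to 100 and the diagonal carries the per-activity rates. Per-subject
rates are computed on the test split only, since learning rows carry no
honest prediction.

## Problem sizes

Desk-scale runs keep the cohort structure and shrink the counts: the
analysis scripts use 4 subjects × 5–8 repetitions at 90 × 72 video; the
end-to-end acceptance check uses 6 subjects × 10 repetitions (noiseless)
and 3 subjects × 3 repetitions for the noise sweep at 60 × 48; the
acceptance script uses 5 subjects × 6–10 repetitions. Full-size frames
(180 × 144 default, up to 720 × 576) and the 20-subject cohort remain
configuration away; only runtime grows.

## Known limitations

* Archetype separability is designed-in; the 100% noiseless recognition
  documents pipeline correctness, not real-world accuracy.
* Horn–Schunck underestimates large displacements (> ~3 px/frame at the
  default texture wavelengths); the generator keeps speeds in range.
* The silhouette is rigid — no articulation, occlusion or background
  clutter; the video chain's robustness to those is untested here.
* The weighted-SD dispersion is descriptive, not an inferential error
  bar; no cross-sensor significance testing is provided.
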