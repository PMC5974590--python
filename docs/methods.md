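# Methods

## Viewing geometry

All quality measures are expressed in degrees of visual angle, so the
pixel→angle conversion is the foundation of everything else. The model: the
eye sits on the perpendicular through the screen center at the
participant's mean recorded eye-to-screen distance *d*; each on-screen
point maps to per-axis angles

    theta_x = atan((x − c_x) · pitch_x / d),   theta_y = atan((y − c_y) · pitch_y / d)

where `pitch` is the physical size of one pixel (from the display diagonal
and resolution, square pixels assumed unless width/height are given
explicitly) and `(c_x, c_y)` is the pixel-grid center. Two-point separations
combine the per-axis angular differences Euclideanly. This per-axis
convention matches how horizontal and vertical precision are reported, and
at the eccentricities a verification layout uses (≤ ~16°) it differs from a
full 3-D great-circle treatment by well under a percent.

No single trigonometric convention reproduces the conventional 14.1°/8.2°
figures for the 480/270 px corner insets exactly at 60 cm (ours gives
13.99°/7.97°, within 1% and 3% respectively); published values of this kind
are typically rounded summaries, so the toolkit documents the ±3% spread
rather than forcing agreement. Pixel coordinates are top-left-origin,
0-based, continuous. Head pose beyond the distance reading is not modeled.

## Sample validity

A sample is valid iff (a) at least one eye's validity code indicates the
eye was found with certainty, (b) gaze coordinates are present, and (c) the
gaze point lies within the screen bounds. Codes follow the 0–4 convention;
the default policy accepts only code 0 and is configurable (e.g. `{0, 1}`).
Missing numeric cells parse to missing values, never zeros; the missing-cell
tokens (empty, `-1`) are configurable because export dialects differ.

## Fixation classification (I-VT)

When an export lacks vendor fixation indices, fixations are classified with
a velocity-threshold filter: threshold 30°/s, minimum duration 60 ms. Two
internals are not pinned down by those two published parameters and were
chosen here:

- **Velocity window** (default 20 ms, ≈7 samples at 300 Hz, centered): the
  speed at a sample is the angular separation between the first and last
  sample of the window divided by the window's time span. This suppresses
  single-sample noise spikes; speed is undefined where the window contains
  an invalid sample.
- **Gap bridging** (default 75 ms, no interpolation): runs of
  below-threshold samples are merged across invalid stretches up to this
  length — enough for blinks and brief dropouts — and bridged samples
  contribute nothing to the centroid. A valid sample at or above threshold
  (strict `<` keeps ties deterministic) always breaks a run.

Vendor I-VT implementations have their own unpublished windowing and gap
rules, so event-boundary agreement with a specific vendor's output is not
promised; the classifier is validated instead against its own contracts and
against simulator ground truth. On strongly autocorrelated noise near the
threshold, any I-VT filter fragments long dwells; the pipeline then scores
the longest fragment, which leaves accuracy unbiased but can mildly
underestimate dispersion relative to the full dwell. No saccade events are
emitted; non-fixation samples are only labeled for diagnostics.

When vendor indices are present they are adopted as-is (one event per
index, invalid samples discarded from the centroid, non-contiguous blocks
merged with a warning).

## Per-trial measures

Per trial, the longest fixation that *started at or after* stimulus onset
is selected (continuation past offset allowed in full; duration ties go to
the earlier event — a deterministic choice where any would do). Accuracy is
the angular distance from that fixation's centroid to the target center.
Precision SD uses population (1/n) normalization of per-axis angular
deviations from the mean; RMS uses the n−1 successive differences. Both
convert each sample's coordinate to an angle first and then difference —
exact under the stated convention. Pairs that straddle a discarded invalid
sample are treated as adjacent; the per-trial `n_bridged_pairs` diagnostic
counts them so users can judge whether dropout inflated RMS (each bridged
pair spans more than one sampling interval of real time).

Precision needs ≥ 2 valid samples; below that the precision fields are
absent with a reason code while the trial can remain valid for accuracy.

## Screening rules

- **Outlier flag:** pool all valid trial accuracies in the analysis group,
  compute grand mean m and sample SD s, flag trials with accuracy
  > m + 1.5·s. Upper tail only (only unusually large errors indicate
  calibration problems) and a single pass — iterating the rule on survivors
  would keep shrinking the set. Scope is the analysis group by default,
  per-participant optionally.
- **Inclusion:** `exclude` only for zero valid fixations; `review` when the
  mean accuracy exceeds a configurable group threshold (default 2°, a
  reasonable bar for child data; adult studies may tighten it) or when more
  than half the valid trials were flagged as outliers. One wild trial among
  four good ones yields `review`, not automatic exclusion — it usually means
  a glance away, and a human should look at the per-target plot or session
  video. Calibration *correction* from the observed error field is
  deliberately out of scope: error directions are typically inconsistent
  within a participant, so discarding is safer than warping.
- **Run comparison:** participants enter the pairing only with valid data in
  both runs, matched at the level of participant means (noted in report
  footnotes); per measure a Wilcoxon signed-rank test (exact small-sample
  null where scipy can, normal approximation with tie correction otherwise).
  Fewer than 5 pairs is flagged low-power but still reported.
- **Group comparison:** per measure, Shapiro–Wilk per group as a normality
  screen, Kruskal–Wallis omnibus, pairwise two-tailed Mann–Whitney judged at
  a fixed corrected α (default 0.008) rather than a p-adjustment procedure —
  reproducing the fixed-α convention rather than recomputing a correction.

The report annotates the vendor-claimed performance band (accuracy
0.4–0.9°, RMS 0.04–0.15°) purely as a labeled reference — the point of the
toolkit being that measured quality often falls outside it.

## Synthetic gaze simulator

The simulator emulates the verification session itself: a 500 ms fixation
cross, then five 2,000 ms target trials in pseudorandom order (center never
first) at 300 Hz, exported in the same TSV dialect the reader consumes.
Gaze is generated in the angular domain and converted to pixels at the
simulated viewing distance, so a correct pipeline inverts it exactly.

- **Calibration error:** a per-participant bias vector added to every dwell
  (optional linear spatial component across the screen).
- **Noise:** per-axis stationary AR(1) Gaussian noise, SD σ, lag-1
  correlation ρ. AR(1) was chosen because it separates the two precision
  measures analytically: E[SD] → σ√(1 − 1/n) while E[RMS] → σ√(2(1 − ρ)),
  exactly the distinction SD-vs-RMS probes. Real tracker noise also
  contains heavier tails, microsaccades and 1/f drift, which the simulator
  does not model — passing tests show the pipeline recovers its generative
  parameters, not that real recordings are this well behaved.
- **Saccades:** linear angular ramps of ~30 ms between dwells, plus a
  latency (250 ± 60 ms, clamped) before each target acquisition during which
  the previous location is still fixated — which is what makes the
  started-after-onset rule meaningful on simulated data.
- **Dropout:** per-sample validity loss (codes → 4, coordinates and
  distances missing).
- **Non-compliance:** with probability 1 − compliance per trial, the dwell
  is replaced by inattentive gaze alternating between looks past the screen
  edge (valid eyes, out-of-bounds coordinates — exercising the off-screen
  rule) and on-screen wanderings too brief (30–55 ms) and too separated
  (≥3° jumps) to ever form a fixation. A non-compliant trial therefore
  yields no valid fixation by construction.
- **Untrackable participants** (toddler presets): a participant-level event
  (probability `untrackable_prob`) setting compliance to 0 and dropout to
  0.6, mimicking sessions that end with no valid fixations; the expected
  exclusion fraction equals `untrackable_prob`.

Cohort presets draw per-participant parameters (Gamma-distributed offset
magnitude with uniform direction, lognormally jittered noise SDs) around
group anchors ordered adult < school-age < toddler in offset and noise,
with toddler compliance < 1. The anchor magnitudes (offset means
0.78°/0.95°/1.35°/1.30°; noise SDs from ~0.11–0.21° per axis; ρ = 0.5 for
adults/school-age so RMS ≈ SD, ρ = 0.25 for toddlers so RMS > SD;
untrackable 20%/14% for the toddler groups) were calibrated once to
reproduce the qualitative between-group ordering reported for this kind of
protocol, not any specific dataset's values; the ground-truth manifest
records every drawn parameter so users can recalibrate. Seeding spawns
per-participant streams from one master seed, making whole study
directories byte-reproducible.

## Problem sizes and numerical choices

The test suite runs desk-scale versions of each guarantee: 1,000 random
fixations for oracle equivalence (tolerance 1e-9°), 200 replicates of
600-sample fixations for the analytic precision limits, a 20-participant
cohort for offset recovery (criterion: |bias| < 3 Monte-Carlo SE), and 50
replicate three-group cohorts of n = 24 for the quality ordering (≥95%
must order correctly) — sizes chosen so the full suite completes in well
under a minute of simulation time while keeping the Monte-Carlo bands
meaningful. Timestamps are de-duplicated keeping the first occurrence after
a stable sort; canonical TSV output writes floats via `repr` and parses
them with correctly-rounded conversion so a write/read cycle is
bit-identical. Degenerate inputs (empty exports, header-only tables, empty
label maps, groups of one, all-zero difference vectors) return empty or
flagged results with warnings rather than raising.

## Known limitations

- Temporal accuracy, robustness/data-loss metrics beyond valid-sample
  counts, and drift *correction* are out of scope.
- The angular convention is one of several defensible ones; absolute
  angles can differ by ~1–3% from other conventions (never within-axis
  orderings).
- I-VT event boundaries will not exactly match any particular vendor's
  implementation.
- The simulator's behavioral model (latency, roaming, untrackability) is
  deliberately minimal — sufficient to exercise every pipeline rule, not a
  model of oculomotor behavior.
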