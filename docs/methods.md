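# Methods

This note documents the models, conventions and numerical choices
behind `octvf`, in the order the pipeline applies them.

## Coordinate conventions

All analysis runs in the right-eye (OD) frame: x > 0 temporal, y > 0
superior, degrees of visual angle.  Grids are ordered row-major from
the most superior row, nasal to temporal within a row.  The 24-2 chart
is generated programmatically (rows at y = ±21, ±15, ±9, ±3 with
half-extents 9, 15, 21, 21 plus the nasal points (−27, ±3)); the 10-2
chart is a literal 68-entry table; 30-2 is the symmetric 76-point
octagon.  The two 24-2 points at (+15, ±3) are the physiologic blind
spot and are excluded from every analysis.

Left-eye (OS) exams are stored in the left-eye chart's own row-major
slot order.  `normalize_laterality` maps them into the OD frame by
reversing each row's indices.  On x-symmetric rows this equals the
coordinate mirror (x, y) → (−x, y); on the asymmetric 24-2 rows that
carry the nasal extension it pairs nasal with nasal and blind spot
with blind spot, which is the standard chart-flip convention and the
only self-consistent reading (the 24-2 point *set* is not mirror
symmetric).  A consequence is that trimming a 30-2 exam to 24-2 first
normalizes OS exams, trims in the OD frame, and mirrors back, so that
trimming and laterality normalization commute.  MD is a spatial mean
and is never permuted; the device-reported MD is kept, not recomputed,
after 30-2 trimming (recomputation is exposed nowhere since no
normative database is modelled).

Volumes are arrays (H, W, D): H the superior-inferior en-face axis
(superior retina at index 0), W the horizontal en-face axis, D depth.
The retinal location of field point (x, y) is (x, −y) — a superior
field point reads the inferior retina — so a vertical volume flip must
always be paired with the vertical label permutation, and the
augmentation and test-time-averaging code treat the two as one
operation.

## Quality control

* Reliability: an exam fails iff max(FP, FN, FL) ≥ 0.33 — the bound is
  inclusive.
* Scan quality: a volume fails iff SSI < 7.
* Upper-eyelid artifact: for the four superior 24-2 rows
  (y = +21 … +3), m_k is the mean of the 3 most nasal thresholds;
  d_k = m_{k+1} − m_k is positive when the upper row is depressed.  An
  exam is flagged iff d_1 > 6 ∧ d_2 > 6 ∧ d_3 > 8 dB, strictly.  Both
  the subtraction direction and the AND combination are config
  options, because the clinical phrasing of the rule is ambiguous; the
  defaults implement the reading that targets upper-lid depression.
  The rule is invariant to adding a constant to all thresholds.
* Anderson–Patella eligibility: a contiguous cluster of ≥ 3
  pattern-deviation points stricter than p < 5% containing at least
  one stricter than p < 1%, or PSD stricter than 5%, or GHT outside
  normal limits.  Contiguity is an 8-neighborhood of one lattice step
  per axis (6° on 24-2/30-2, 2° on 10-2); clusters never cross the
  horizontal meridian and blind-spot points never participate.

## Label construction

Time is measured in years of 365.25 days from the OCT date, so the
fitted intercept is the label and the construction is equivariant to
shifting all dates.  With ≥ 2 exams carrying a point the label is the
OLS line value at the OCT date; a positive fitted slope is clamped to
zero, and the zero-slope refit is the series mean (the least-squares
solution under the constraint — not the unconstrained intercept).
With exactly one exam the label is that exam's value iff the OCT lies
within 6 months; with none, the entry is masked.  Exams on a single
duplicated date fall back to the mean.  Thresholds are clamped to
[0, 33] dB, MD (regressed as its own series, not recomputed from the
regressed points) to [−33, 0] dB; clamping applies uniformly,
including single-exam pairing.

The validity period is 6 months × n tests; a pattern block whose
nearest exam (configurable: chronologically last) is further from the
OCT than that is fully masked.  A month is 365.25/12 days.  The
122-vector layout is fixed: indices 0–51 the 24-2 points, 52 the 24-2
MD, 53–120 the 10-2 points, 121 the 10-2 MD.  Masked slots hold the
sentinel 0, which is inert by construction: the loss and every metric
multiply residuals by (1 − mask), a property the tests verify by
perturbing masked slots.

Each OCT scan of an eye yields its own paired sample; an OCT with no
usable VF block is rejected.

## Synthetic data generator

The generator stands in for a private clinical cohort and emulates the
statistical structure the method assumes, not retinal physics:

* Thickness: a smooth base (~100 µm-like units with a gentle
  perifoveal bulge) minus 1–2 arcuate Gaussian defects placed on
  superior and/or inferior arcs 7–16° from fixation (σ 4–9°, depth
  15–70 thickness units).  70% of eyes carry defects
  (`defect_prevalence`).
* Structure-function coupling: sensitivity = 33 dB − gain × local
  thickness deficit at the point's retinal location, clamped to
  [0, 33]; the default gain of 0.5 dB per thickness unit makes deep
  defects bottom out, producing the floor effects real fields show.
* Longitudinal series: 5 exams at 180-day intervals; per-point slopes
  are a non-positive eye-level rate (mean −0.6, SD 0.5 dB/year,
  clipped at 0) weighted toward already-damaged locations; test-retest
  noise is Gaussian (default SD 1.5 dB; the recovery benchmark uses
  1.0 dB); 5% of exams are unreliable, 5% of scans low-SSI.
* Volumes: the first bright band's axial extent follows the thickness
  field; deeper fixed bands mimic outer retina; Gaussian speckle-like
  noise (SD 0.05) on top.  OS eyes are mirrored and their exams
  produced in the device frame, so ingest-side normalization is
  exercised.
* Eyelid artifacts: injected by depressing the four superior rows by
  depth × (1.8, 1.15, 0.65, 0) dB.  At the reference depth of 15 dB
  the nasal-mean drops are (9.75, 7.5, 9.75) dB, safely beyond the
  6/6/8 rule even under 1 dB test noise — the profile models a lid
  covering the top rows progressively more deeply.
* The en-face frame spans ±28° so every 24-2 point maps inside the
  scan.  This deliberately removes the real-world coverage limitation
  of macular scans for temporal-peripheral points; passing recovery
  tests therefore say nothing about points whose nerve-fiber
  trajectories a real 9 mm × 9 mm scan would miss.  Likewise the
  generator has no nerve-fiber trajectory geometry, no media opacity,
  and its pattern-deviation categories are deterministic surrogates
  derived from true loss, not normative statistics.

All randomness flows through one `numpy` Generator seeded from the
config; identical seeds give bit-identical datasets.

## Regressor and training

The regressor is a numpy implementation of stacked (3×3×3, stride-2)
convolution + batch-norm + ReLU blocks, global average pooling, 30%
inverted dropout, and a single linear map to the 122 outputs — no
hidden layer in the head.  Backward passes are hand-derived and
checked against central finite differences in the test suite.  Two
design choices matter:

* Two fixed en-face coordinate channels are concatenated to the input
  inside the model.  A GAP head is translation-blind; the coordinate
  channels let convolutional features encode *where* a structural
  change sits, which spatially indexed targets require.  They are part
  of the model, applied after any input flip, so the augmentation
  contract is unaffected.
* The default `small3dcnn` uses channels (12, 24, 48, 48)
  (~1.1 × 10⁵ parameters), chosen for held-out recovery accuracy at
  64 × 64 × 32 input on one CPU.  An `efficientnet3d_b0` config name
  selects a deeper member of the same block family for larger inputs;
  it is not a literal EfficientNet port.

Preprocessing trilinearly resamples each volume to the configured
input shape and min-max normalizes it to [−1, 1] (a constant volume
maps to zeros).  Targets are z-scored per output position with
statistics of unmasked training entries only (SD floor 10⁻³ dB; a
position with no unmasked training entry is a hard error naming the
position).  Optimization is Adam, batch 4, learning rate linear from
6e−4 to 1e−3 over epochs 1–3 and back to 6e−4 over epochs 3–8
(endpoints inclusive, epoch granularity); training runs the 8
scheduled epochs and returns the state of the epoch with minimum
validation masked loss.  Vertical flipping is a 50% training
augmentation plus a deterministic two-view average at inference; the
alternative reading (an always-on deterministic flip) is reachable by
setting the flip probability, but flipping features without permuting
labels is not supported because the targets are spatially indexed.

Folds are patient-wise: patients are shuffled once by seed into 10
parts; fold i tests part i, validates part i+1, trains the remaining
eight.  Every sample of a patient stays in one set per fold and every
patient is tested exactly once across folds.

Determinism: one seed governs initialization, shuffling, dropout and
augmentation; repeated runs give bit-identical validation losses under
a fixed BLAS thread configuration.

## Evaluation

Error statistics follow the per-pair-then-average convention: RMSE
(and, for internal consistency, MAE) is computed per OCT-VF pair over
its unmasked points of one pattern block, then averaged across pairs;
reported "± " values are across-pair standard deviations.
Correlations pool all unmasked (prediction, label) values; per-point
coefficients are available as an option.  Bland–Altman uses
d = estimated − actual, bias ± 1.96 × sample SD (ddof = 1), and the
Pearson correlation of pair means with d as the proportional-bias
measure.  Severity strata close their bounds as mild MD > −6,
moderate −12 < MD ≤ −6, severe MD ≤ −12 dB.  The Mann–Whitney U test
enumerates all group assignments exactly when min(n) ≤ 8 and the
pooled values are tie-free, otherwise uses the tie-corrected normal
approximation; p-values are Bonferroni-multiplied (default m = 6, the
number of tabulated comparisons) and capped at 1.  The quadratic
severity-vs-error fit is degree-2 least squares with the Spearman ρ of
|error| against severity; constant errors are surfaced as an error
because the rank correlation is undefined.

## Experiment harness

`run_experiment` builds two training cohorts from one population —
curated (Anderson–Patella-eligible eyes, the manually cleaned analog)
and comprehensive (all QC-passing eyes, cleaned only by the automatic
artifact rule) — trains both under identical folds and
hyperparameters, evaluates both on the curated-eligible test subset,
and compares their per-pair MAE distributions.  The contrast is
structural (inclusion rules); no claim is made that synthetic effect
sizes mirror clinical ones.  Stage outputs are cached content-addressed
by the full config hash, so a rerun without config changes is a no-op;
a per-fold cohort without train or validation samples (possible in
tiny populations) is recorded as skipped.

## Problem sizes

Defaults are sized for a single CPU: test configurations use 16³–64³
volumes and ~12-patient populations; the recovery benchmark trains one
fold of 150 patients at 64 × 64 × 32 for 8 epochs in a few minutes.
The full-scale configuration of the harness (224 × 224 × 128 input,
10 folds) is accepted by the same code paths but is not exercised by
the test suite.

## Known limitations

* The artifact rule cannot distinguish true superior glaucomatous
  defects from lid artifacts; it is a training-data filter, not a
  clinical classifier.
* Simplified MD is an unweighted deficit mean against a flat baseline;
  no age correction, variance weighting or normative deviation maps.
* The numpy regressor is CPU-bound and intentionally small; it
  demonstrates the training contract and recovers strong synthetic
  coupling, not clinical-grade accuracy.
* Exact Mann–Whitney enumeration is skipped in the presence of ties
  (falls back to the corrected normal approximation).
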