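# Methods

This note documents the models, numerical choices and open design
decisions behind `pupilwalk`, and what the synthetic validation does
and does not establish about real recordings.

## Stimulus model

The walker is a stylized parametric stand-in for motion-captured
point-light stimuli: 15 markers (head, thorax, pelvis, and left/right
shoulders, elbows, wrists, hips, knees, ankles) animated around a
static skeleton by sinusoidal trajectories with a fundamental gait
frequency plus a first overtone (the overtone sharpens the swing
profile). Arms and the contralateral leg share phase; vertical bounce
runs at twice the gait frequency; ankles get an additional once-per-
stride lift. The walker walks in place, faces 45° (the `left45`
direction is the exact x-mirror of `right45`), and uses screen-pixel
coordinates (origin top-left, y down, 0-based frames).

Emotion is a score on a happy–sad axis in SD units (sad −6 … happy
+6) that linearly interpolates cadence (0.75–1.25 Hz before
calibration), limb amplitude (±35%), and posture (head/shoulder droop
and forward slump for sad walkers). The only quantitative anchors are
the per-emotion mean dot speeds — 5.76, 4.14, 3.21 px/frame for
happy, neutral, sad at 60 frames/s — which the generator hits by
fixed-point rescaling of the gait frequency until the mean per-frame
displacement matches the target (converges to ~1e-6 relative, far
inside the 1% contract). Between the anchors the default target speed
interpolates piecewise-linearly. No claim is made that coordinates
match any motion-capture dataset; what matters downstream is the dot
count, the emotion-graded speed/amplitude/posture, and that the
transforms below are exactly valid.

Generated positions are snapped to a 2⁻¹⁶ px grid. This is invisible
at stimulus scale but puts positions and transform offsets on a
common dyadic lattice, so translation (scrambling) and reflection
(inversion) are exact in float64: inversion is a bit-exact involution
and scrambling preserves frame-difference vectors bit-for-bit.

### Transforms

* **Inversion** reflects y about the display-box vertical midline
  (falling back to the sequence bounding box when no display box is
  carried). An isometry: per-dot speed profiles are unchanged.
* **Scrambling** translates each dot's whole trajectory rigidly so its
  first-frame position is uniform over the axis-aligned bounding box
  of the source sequence (all frames, all dots). Whole-trajectory
  translation, rather than per-frame relocation, is the reading under
  which local motion is preserved exactly while configuration is
  destroyed. Whether the box should constrain the entire trajectory
  rather than only initial placement is genuinely open; initial
  placement was chosen as the minimal reading. Scramble draws are
  seeded per call, so per-trial versus fixed-across-trials usage is
  the caller's choice.
* **Acceleration removal** reparameterizes each dot to constant speed
  along its own piecewise-linear path: output frame k sits at arc
  length k·L/(n−1) along the path of total length L. "Speed" here is
  arc length traveled per frame. That definition is forced, not a
  convenience: gait dots reverse direction twice per cycle, and on a
  self-reversing path no on-path, endpoint-preserving resampling can
  make chord lengths (per-frame displacement magnitudes) constant —
  chords straddling a turning point are necessarily short. Under the
  arc-length definition the transform is exactly constant-speed,
  conserves per-dot path length and mean speed by construction, and
  preserves endpoints. Validation measures traversal independently by
  monotone closest-point projection of output frames onto the
  original polyline (`path_arc_positions`); the measured per-dot speed
  CV is ~1e-14. Dots with zero path length pass through unchanged.

## Synthetic experiment generator

Each trial trace at 500 Hz over −200…4000 ms is

```
x(t) = b_j + E(t) + s_j · f_c(t) + n(t)
```

* `b_j` — subject baseline, N(1000, 50²) a.u. (arbitrary units;
  removed by baseline correction).
* `E(t)` — shared evoked transient: gamma-shaped dilation
  (t/t_p)²·exp(2(1−t/t_p)), peak 0.5 a.u. at t_p = 900 ms. It gives
  realistic condition-independent structure and cancels exactly in
  paired contrasts; no fidelity to a specific pupil response model is
  claimed.
* `f_c(t)` — condition effect: a logistic ramp reaching plateau over
  300 ms, hard-zeroed before onset so the ground-truth window is
  well-defined. Defaults: happy +0.30 a.u. from 1750 ms, sad −0.24
  a.u. from 1850 ms, neutral null; effects sustain to stimulus
  offset.
* `s_j` — subject sensitivity, 1 + 1.1·z; one multiplier scales all
  condition effects, so individual differences are a single trait.
* `n(t)` — AR(1) noise, coefficient 0.99 per 500 Hz sample,
  innovation SD 0.12 a.u. A single autoregressive stream (rather than
  AR(1) plus separate white noise) keeps the residual lag-1
  autocorrelation identifiable and equal to the configured
  coefficient.

Blinks arrive as a Poisson process (0.10/s, durations 100–300 ms) and
mark samples invalid with undefined (NaN) diameter; the on-disk
writer emits hardware zeros instead, and the reader treats both as
invalid.

AQ scores come from a latent bivariate normal coupling the trait
deviate to the sensitivity deviate at r = −0.47, mapped
rank-preservingly to integers via 20 + 7z, clipped to 0–50. The
integerization and clipping attenuate the realized correlation by
~1%.

**Calibration of the default amplitudes.** The paradigm is powered
for moderate within-subject effects at n = 24. The default
amplitude/noise/sensitivity split was chosen (once, analytically,
then confirmed by simulation) so that (i) the scalar happy-vs-neutral
contrast lands at d_z ≈ 0.6–0.8, the moderate range the design
targets; (ii) between-subject variance in the modulation scores is
dominated by the sensitivity trait rather than measurement noise, so
the AQ coupling is recoverable with only mild attenuation (mean
estimated r ≈ −0.42 for a generative −0.47); and (iii) the cluster
test detects the happy-vs-neutral window in ≥ 90% of experiments.
Measurement noise attenuating recovered correlations is a real
phenomenon, and the generator reproduces it at a realistic magnitude.
No amplitude scale is claimed for real recordings — pupil units are
arbitrary throughout.

What the simulator does **not** model: gaze dynamics, microsaccades,
the pupil light reflex, luminance coupling, slow session drift,
unequal trial counts by design, or missing conditions. Passing
recovery tests therefore demonstrates correctness of the analysis
code under the stated generative assumptions, not robustness of the
pipeline to every artifact of real eye-tracking data.

## Preprocessing decisions

* Interpolate-vs-discard: invalid runs are padded by 50 ms per side
  (eyelid closure corrupts diameter estimates around the detected
  blink), runs ≤ 500 ms are linearly interpolated from flanking valid
  samples, longer runs discard the trial, as do > 25% total invalid
  samples or a run touching a trace boundary (no flanking sample to
  interpolate from). All thresholds are configurable; every discard
  is logged with its reason, and conservation (every trial in the
  matrix counts or the log) is tested.
* The ±3 SD trial screen operates per subject on trial means, pooled
  across conditions — screening within condition could bias the
  condition contrasts the pipeline exists to estimate. Population SD
  (ddof = 0), single pass, strict inequality.
* Baseline window is half-open [−200, 0) ms on raw samples; bins are
  50 ms, timestamped by center, assigned by time so sample rates that
  do not divide evenly into bins remain valid; bins average valid
  samples only.
* The scalar "mean pupil size" averages bins over the 4000 ms
  stimulus window only (onset to offset), not the baseline.

## Cluster permutation test

Forming threshold: the two-tailed pointwise critical t at α = .05
with df = n−1 (the test runs on the 20 Hz bins; the 50 ms window
granularity of reported effects implies bin-level testing). Clusters
are maximal same-sign supra-threshold runs; a sign change without a
sub-threshold gap splits the run. Zero-variance bins map to ±∞ t with
the sign of the mean difference (supra-threshold by construction),
and to 0 when the differences are identically zero.

The null statistic is the permutation maximum of |cluster mass| —
max-statistic family-wise control, the conservative standard choice
when the alternative (per-cluster nulls) is not specified. Sign flips
are drawn per subject with probability ½; when 2ⁿ ≤ the permutation
budget the full set of patterns is enumerated instead and p = #{null
≥ |mass|}/2ⁿ is exact (the identity pattern guarantees p > 0). In
Monte-Carlo mode the add-one estimator (1 + count)/(1 + B) is used.
Counting uses a 1e-9 relative slack so the identity permutation,
recomputed through different arithmetic, always counts. Type-I
calibration over 500 null experiments lands inside the binomial band
around the nominal 5%.

An omnibus three-condition time-course test is deliberately not
implemented; the analysis design uses pairwise contrasts only.

## Scalar statistics

ANOVA decompositions (including Mauchly's W and the
Greenhouse–Geisser ε from the double-centered covariance) are
delegated to pingouin and cross-checked in the test suite against
explicit sum-of-squares oracles; degenerate inputs (no within-subject
variation) are defined as F = 0 rather than 0/0. Both uncorrected and
GG-corrected p are always reported — published analyses alternate
between conventions, so `p_preferred` applies the correction exactly
when Mauchly's test rejects at .05, and either convention can be read
off the result. Partial η² uses uncorrected dfs (GG rescales dfs but
not F or η²).

Cronbach's α for two occasions uses the raw covariance form
2(1 − (s₁² + s₂²)/s²_total): the standardized two-item formula
2r/(1+r) is inconsistent with published (r, α) pairs for this
paradigm unless variances differ across occasions, so the raw form is
the one that can reproduce them. The accuracy-vs-chance test is a
two-tailed one-sample t against 0.5 (chance level configurable).

The AQ correlations take the per-subject difference of scalar mean
pupil size over the stimulus window (happy−sad, happy−neutral,
sad−neutral) as the modulation scores; "dilation effect" is not given
a formula in the source conventions, and the full-window scalar
difference is the assumption used consistently here.

## Pipeline and reproducibility

All randomness derives from one seed through `numpy.random.
SeedSequence` spawning (31-bit children), split per stage; identical
config + seed gives byte-identical reports, and the report carries a
provenance block (seed, config hash, package version). Reports
serialize to JSON and validate against the schema shipped at
`pupilwalk/data/statsreport.schema.json`.

## Problem sizes in the validation studies

The replication studies use 500 null experiments at the analysis-bin
level (24 × 80, AR(1) bins, 1000 permutations) for type-I
calibration, 20 six-subject datasets for enumeration agreement, 100
full-pipeline experiments for window recovery and 200 for
AQ-correlation recovery — sizes at which the binomial/Monte-Carlo
error of each summary is small relative to its acceptance band.

## Known limitations

* The gait model is qualitative; only speeds are calibrated.
  Inversion/scrambling/de-acceleration are exact regardless.
* Exact enumeration is all-2ⁿ, practical to n ≈ 20; beyond that the
  add-one Monte-Carlo p has resolution 1/(B+1).
* The GG-corrected mixed-ANOVA p applies ε from the within-subject
  term to the interaction dfs; for strongly unbalanced groups treat
  the corrected interaction p as approximate.
* `read_dataset` assumes the documented TSV dialect (one file per
  subject, global clock, hardware zeros for invalid samples); vendor
  binary formats are out of scope.
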