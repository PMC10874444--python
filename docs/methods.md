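# Methods

## The measurement model

The package estimates a perceptual scale for PAL distortions from ordinal
data.  Each trial presents three distortion conditions — choice 1, anchor,
choice 2 — and records which choice appeared more similar to the anchor.
Soft ordinal embedding (SOE) assigns each stimulus a coordinate vector
`x_i` so embedding distances respect the judgments: with winner `w` and
loser `l` relative to anchor `a`, the loss is

    L(X) = Σ_r max(0, δ + ‖x_a − x_w‖² − ‖x_a − x_l‖²)².

Squared distances inside the hinge and a squared hinge keep the objective
smooth almost everywhere.  The margin δ = 1 fixes the otherwise free global
scale of the solution and nothing else: rescaling X by √δ maps the loss
landscape onto itself, so the choice of δ is immaterial to everything
downstream (alignment renormalizes).  An embedding is identified only up to
a similarity transform; every downstream consumer (accuracy, alignment,
normalization, models) is invariant to shift, rotation/sign, and positive
rescaling, and the test suite checks this.

**Optimization.**  Full-batch first-order minimization (L-BFGS-B with the
analytic gradient; loss non-increasing across accepted line-search steps,
stopping at relative loss change < 1e-8 or 2000 iterations) from
`restarts` standard-normal initializations (default 10; 3 inside
cross-validation folds); the restart with the lowest converged loss wins.
On the 11-stimulus design a single fit takes milliseconds.

**What the data can and cannot determine.**  With the study design — every
3-subset of the 11 stimuli presented twice with one (randomized) anchor per
subset — a subject's 330 core responses impose 165 distinct comparisons
between pairwise gaps.  These constraints are purely ordinal: the set of
1-D configurations satisfying *all* of them (loss exactly 0, triplet
accuracy 1.0) is a region, not a point, and configurations inside it can
differ from the generating scale at Pearson r ≈ 0.96 when the true values
are unevenly spaced (tight cluster near the undistorted end, one strong
outlier lens).  Single-subject metric recovery is therefore bounded near
r ≈ 0.97 regardless of estimator; averaging a 13-subject cohort with
per-subject anchor randomization decorrelates the slack and recovers the
mean scale at r ≈ 0.985–0.995.  Users should treat single-subject scales as
ordinal with approximate metric meaning, and the average-observer scale as
the metrically reliable object.

**Accuracy.**  Triplet accuracy is the fraction of responses whose winner
is strictly nearer the anchor; exact distance ties count 0.5, which is
unbiased for degenerate configurations.  An empty response list embeds to
an arbitrary configuration with accuracy 1.0 by convention (with a
warning); an empty list passed to the accuracy function itself is an error.

**Dimension selection.**  k-fold cross-validation (default k = 10, seeded,
catch trials excluded) scores held-out triplet accuracy per candidate
dimension; the smallest dimension within one standard error of the best
mean is selected.  The one-SE rule and the fold count are package choices —
the protocol's description of "the lowest dimension that still predicts
well" does not pin them down.  A caveat found during development: under
logistic decision noise (σ = 0.05) the 1-D hinge optimum sacrifices some
train accuracy on tightly spaced stimuli (margin pressure distorts the
local order), which a 2-D fit relieves; the one-SE rule then admits
dimension 2 for roughly 15% of synthetic subjects even though the generator
is exactly one-dimensional.  Selection is reliable for clean observers and
for the cohort as a whole, but "every subject selects 1-D" is not a
guaranteed outcome at that noise level.

**Bootstrap.**  Scale robustness is quantified by B resamples of the
responses (with replacement, same size), each re-embedded and aligned to
the point estimate by 1-D Procrustes (shift, positive scale, sign) before
computing per-stimulus standard deviations.  Refits use common random
numbers — the same initializations for every resample — so the spread
measures data variability rather than optimizer placement inside the
feasible region.  Even for a perfectly consistent observer the spread does
not vanish: resampling drops ~37% of the ordinal constraints and the
weakly pinned extreme lenses wander within the enlarged feasible set
(max per-stimulus sd ≈ 0.06–0.07 on the normalized scale at B = 50).

## Alignment and normalization

Per-subject 1-D scales are aligned by generalized Procrustes analysis
restricted to 1-D similarity transforms: each scale is regressed onto the
current reference (sign free, magnitude positive after sign extraction),
the reference is replaced by the mean of the aligned scales and
re-standardized to zero mean and unit root-mean-square — without that
constraint GPA collapses all scales toward zero — and the loop runs to a
1e-12 max-norm fixed point.  Alignment is invariant (to ~1e-6) under
subject reordering and under per-subject affine/sign mangling of inputs.

Normalization applies **one common affine map** to all subjects: subtract
the cross-subject mean of the undistorted condition, divide by the mean of
the (`Sph` 5 / `Add` 3) lens minus that zero mean.  Afterwards the two
anchor means are exactly 0 and +1; individual subjects need not hit the
anchors, so between-subject spread is preserved.  The strongest lens maps
to +1 (not −1) by convention.

## The synthetic observer

The generator defines the study conditions for every test:

* **Ground-truth scale** `s(Sph) = a + b·c^Sph` per `Add` group with
  defaults a₁ = −0.33, b₁ = 0.35 (Add 1), a₃ = −0.21, b₃ = 0.25 (Add 3),
  shared base c = 1.6, reference fixed at 0.  This produces the qualitative
  regime of interest: sign change across Sph = 0, steeper growth for
  positive Sph, compensation by Add at negative Sph, near-equal Add and Sph
  influence close to Sph 0.  The offsets place the Sph = 0 lenses slightly
  above the reference (0.02 and 0.04) so that perceived distortion
  increases strictly with Add near Sph 0 and no two stimuli coincide —
  coincident values would force a "noiseless" observer to answer some
  triplets by coin flip.
* **Decision model**: P(choice 1) = λ/2 + (1 − λ)·logistic((d₂ − d₁)/σ)
  with distances on the ground-truth scale; σ = 0 degenerates to argmin
  with fair-coin tie breaks.  Default σ = 0.05 scale units yields overall
  response accuracies around 0.92–0.95, a plausible human regime; λ = 0 by
  default.
* **Design**: each synthetic subject receives an independently seeded trial
  list — trial order and the anchor of each 3-subset randomized per subject
  (the protocol fixes neither).  Catch trials (20% of the total; 83 of 413)
  pair an exaggerated lens (Sph 8, Add 1, so it lies on the observers'
  scale) as one of the choices — never the anchor — with mildly or
  undistorted companions; its scale value (≈ 14.7) makes the correct answer
  unambiguous, and the severity index of the parametric distortion fields
  confirms it also dominates physically.
* **Head motion**: dynamic observers oscillate pitch (nodders) or yaw at
  A ≈ 15°, f ≈ 0.5 Hz (mean |velocity| = 4Af ≈ 30°/s); all other
  components carry Gaussian jitter smoothed with a 0.15 s kernel and
  rescaled to sd 0.5°, which bounds jitter velocity near 2°/s — far below
  the 10°/s classification threshold.  The default cohort mirrors the
  studied population: 7 dynamic (5 pitch, 2 yaw), 6 static, interleaved so
  small cohorts still mix classes.
* **Gaze**: binocular (lon, lat) are independent Gaussians (per-subject
  center near the lower meridian, spread 3–9°); per-eye vectors are the
  binocular direction swung ±1.5° about the sample's local vertical axis,
  so the eyes' mean is exactly the binocular direction.

What the generator does **not** emulate: learning or adaptation across
trials, motion-contingent cues (a single scale drives both static and
dynamic observers — consistent with the finding that behavior does not
shape the scale), lapse clustering, eye-tracker noise spectra, fixation
sequences, or any coupling between head pose and gaze.  Passing tests
demonstrate that the *analysis* is correct under these idealized
conditions, not that real observers behave this way.

## Stimulus model

The ray-traced distortion fields of real PAL designs are proprietary; the
package substitutes a two-term parametric field over head-relative
longitude/latitude (degrees, 1° lattice): a cubic radial term
`sign(Sph)·k₁·|Sph|·r³·r̂` (pincushion for positive, barrel for negative
far power) plus a lower-field term `k₂·Add·max(0, −lat)·r·r̂` carrying the
near-zone asymmetry.  Constants k₁ = 4·10⁻⁶ deg⁻²·dpt⁻¹ and
k₂ = 2·10⁻⁵ deg⁻¹·dpt⁻¹ put the peak displacement at the rim of the
116° × 80° frame ellipse at a few degrees for the strongest lens and keep
the radial term dominant so the severity ordering (RMS displacement inside
the aperture) is strictly increasing in |Sph| and topped by the catch
lens.  These constants are simulator configuration, not claims about any
lens; the fields anchor the synthetic scales physically and exercise the
field/warp/severity interfaces.

## Behavior analysis

Orientation quaternions are decomposed with intrinsic y-x-z order (yaw
about the vertical axis, then pitch, then roll) in a right-handed frame
with y up and z backward; at gimbal lock the roll is set to 0.  The frame
convention is stated because the protocol names only the rotation order.
Angles are unwrapped (period 360°) before differencing; derivatives are
central in the interior, one-sided at the ends.  Classification is
strictly-greater-than 10°/s on any component's mean |velocity|.

Gaze area uses a fixed-bandwidth (2°) isotropic Gaussian KDE on the
(lon, lat) plane, computed by binning at 0.5° and convolving — exact up to
the bin width.  The smallest superlevel set holding 95% of the planar KDE
integral is found by sorting cells by density; its solid angle is
integrated with cos(lat) weighting and reported as a percentage of the
half-sphere (2π sr).  Against the closed form for a smoothed isotropic
Gaussian (π·χ²₂(0.95)·(σ² + h²)) the estimate agrees within a few percent.

Mann–Whitney U tests enumerate the exact permutation null (midranks, so
ties are handled exactly) when the pooled sample size is ≤ 12 — C(12,6) =
924 assignments — and use the tie-corrected normal approximation
otherwise.  The behavior OLS regresses normalized scale values on `Sph`,
`Add`, movement class (0/1), gaze area, and all interactions (16 terms);
continuous predictors are centered; p-values are two-sided t-tests without
multiplicity correction.  Rank deficiency is reported with the offending
columns named; note the four subject-level regressors require at least
four (in practice five or more) subjects.  Because the OLS mean structure
is linear while the true scale is exponential in `Sph`, lack-of-fit
inflates the residual variance on realistic cohorts and the behavior-term
tests are conservative there; the null-calibration check therefore uses a
linear generating model, under which the tests are exact.

## Problem sizes and reproducibility

All simulations are seeded; identical configurations produce byte-identical
summary artifacts.  The test suite and the acceptance script use: the
canonical 11-stimulus design (413 trials per subject), cohorts of 13
observers, 10-fold CV over dimensions {1, 2, 3} (3 restarts per fold), 10
restarts for final embeddings, 5 cohorts for model-comparison medians, 200
replicate cohorts for the null-calibration rate, 30 s head traces at 90 Hz,
and 10⁴-sample gaze clouds where a closed form is checked (2000 in the
pipeline).  The acceptance script completes in a few minutes on one CPU.

## Known limitations

* Single-subject scales are ordinally exact but metrically underdetermined
  (see above); cross-subject means are the reliable metric object.
* The exponential model is fit per `Add` group on training means with the
  reference predicted as exactly 0; pooling subject rows instead would
  weight subjects by their deviation from the mean.
* The bagged-tree ceiling (100 unpruned trees, all features per split,
  seeded) is a reference point, not a tuned model.
* The parametric distortion fields share one field for both eyes and model
  no blur or astigmatism; binocular disparity of distortions is out of
  scope.
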