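# Methods

This note documents the models, conventions and design choices behind
`silhofm`: what the synthetic cohort emulates, how silhouettes are
measured, what the fat-mass models assume, and which numerical
decisions matter when reproducing results.

## Synthetic cohort

The generator produces body-composition records and matching rendered
silhouettes so that the whole measurement chain can be validated
against exact ground truth.

**Composition marginals.** Per gender, total fat mass (FM) and
abdominal (lumbar 2–5) fat mass follow lognormal distributions
truncated to the configured plausibility ranges; stature and body
weight follow normals truncated at ±3 SD. Defaults (means ± SD and
ranges) describe a mixed adult cohort with a wide adiposity spread:
females FM 22.8 ± 10.9 kg on [8.6, 59.2], abdominal FM 2.45 ± 2.0 kg on
[0.24, 6.9], stature 163.6 ± 6.7 cm, weight 66.8 ± 13.1 kg; males FM
17.0 ± 7.5 kg on [6.2, 33.0], abdominal FM 1.94 ± 1.41 kg on
[0.35, 5.0], stature 178.8 ± 7.0 cm, weight 80.1 ± 11.5 kg.

Truncation changes moments, so the pre-truncation (μ, σ) are calibrated
numerically — the truncated mean is solved exactly for every σ (the
truncated mean is monotone in μ), and σ is chosen so the truncated SD
hits the target. Two abdominal targets sit above what a truncated
lognormal can produce at the configured mean and range (the family's SD
ceiling there is ≈1.87 kg for females, ≈1.31 kg for males); in that
case the generator matches the mean exactly and takes the
SD-maximising member of the family. A side effect of the heavy
truncation is a right-spread, J-ish marginal shape for abdominal fat —
acceptable for validation purposes, but not a claim about real abdominal
fat distributions.

**Dependence.** Records are sampled through a Gaussian copula with
inverse-CDF marginals: latent correlations 0.9 (FM ↔ abdominal FM) and
0.75 (FM ↔ weight), each marginal exact by construction. Rejection is
used only for the (practically impossible) abdominal ≥ total ordering
violation. An earlier joint-rejection sampler was abandoned: rejecting
the heavily truncated abdominal coordinate selected a narrow band of
its latent variable and, through the 0.9 correlation, biased every
other marginal.

**Shape map.** Eight body segments (head, neck, chest, belly, hip,
thigh, calf, ankle) get sagittal depths [cm] from a linear map
`depth = base + c_fm·FM + c_ab·FM_abdominal`, with the belly dominated
by abdominal fat (c_ab = 1.2 cm/kg) and chest/hip/thigh tracking total
fat. Independent Gaussian "build" noise (SD 0.25 cm per segment)
represents individual variation not explained by fat mass. Depths are
independent of stature; the normalised features inherit a 1/stature
factor through the frame span, which is the main irreducible noise
source when predicting FM from features alone. The map is deliberately
the simplest family that makes monotonicity (more fat ⇒ wider belly)
and parameter recovery exactly testable; it is a stand-in for the
unknown true shape–composition relation, not a reconstruction of it.

**Rendering.** A body of stature *L* is drawn as a single vertical
column; the per-row width follows a monotone PCHIP interpolation
through keypoints placed at fixed stature fractions. The measurement
sites are exact local width maxima at known fractions (chest 0.264,
belly 0.411, thigh 0.613, calf 0.815 of stature), each flanked by two
knots at 99% depth so the discrete extremal run is symmetric about the
true row. The neck (0.155·L) is the unique width minimum in the upper
body; the eye line is defined at 40% of head height (crown to neck);
the malleolus line at 2% of body height above the sole. Rows are
filled with an exactly rounded run length (`round(2·halfwidth)` pixels)
so per-row quantisation never exceeds half a pixel. Ground truth
(landmark rows, occupancy, site widths) is computed directly from the
rendered mask and the analytic keypoint rows — independent of the
detection code it validates.

Pose jitter multiplies each keypoint depth by `1 + jitter·N(0,1)` and
adds a small whole-body lean (SD = 50·jitter degrees, pivoting at the
feet). Jitter does not move the vertical keypoints, so ground-truth
rows are unaffected.

**QC violation renders** perturb exactly one acquisition rule each:
head sheared 15°, an arm strip leaving the torso at the shoulder,
a split leg column below the hip, a half-scale body, or a zero top
margin. The perturbations are geometrically disjoint by construction,
which is what makes per-rule QC discrimination testable.

## Conditioning and acquisition QC

Segmentation is threshold-based (fixed value or Otsu) and assumes
separable intensities — the conditioning contract starts at
high-contrast input; photographs with arbitrary backgrounds are out of
scope. After thresholding, the largest 8-connected component is kept
and interior holes are filled, yielding the single homogeneous
silhouette. Masks are boolean in memory and 255/0 8-bit PNG on disk.
Resolution standardisation rescales to a fixed pixel count (default
5·10⁶) preserving aspect ratio and is idempotent at the target.

QC checks (all computed, none short-circuiting):

| check | operationalisation | default tolerance |
|---|---|---|
| head_not_horizontal | principal axis of the crown-to-neck region vs vertical | 8° |
| arm_not_alongside | fraction of rows with ≥2 foreground runs in the neck-to-belly band | 0.10 |
| legs_not_aligned | fraction of rows with ≥2 runs below 62% of body height | 0.15 |
| subject_too_small | eye-to-malleolus span over image height | 0.50 |
| touching_border / multiple_bodies | direct mask inspection | — |

The tolerances are package defaults, chosen once for the synthetic
acquisition geometry; they are config fields, not empirical constants.
The limb checks use run counts rather than a protrusion-width ratio: a
limb away from the body reads as a second foreground run, which is
robust against the natural width bumps (chest, belly) that defeat
simple width-outlier rules.

## Geometry

Coordinates are 0-based, row-major, origin top-left; row and column
intervals are half-open for counting. Landmark detection places the
malleolus at a 2% offset above the lowest row, estimates head height
from the neck minimum (midpoint of the minimal run — discretisation
flattens smooth extrema into runs, and the run midpoint is the stable
sub-row estimate), puts the eye line at 40% of head height, seeds the
four site rows at fractions 0.22 / 0.38 / 0.60 / 0.82 of the
eye–malleolus span, and refines each to the local width-maximum run
midpoint within ±3% of span. On jitter-free renders this recovers the
ground-truth rows within ±2 rows at 5 MP.

The virtual frame spans eye to malleolus; its width is
`round(frame_fraction · span)` (default fraction 0.4), centred on the
silhouette's column centroid and clipped to the image. A silhouette
wider than the frame is an explicit error (raise `frame_fraction`).
Occupancy supports two readings — foreground/background (`ratio`,
default) and foreground/total (`fraction`) — because both appear in
informal descriptions of occupancy-style features; neither is asserted
as canonical, and the choice is a config switch.

Feature invariances are design targets, verified by test: ≤1% relative
change across 2/5/8 MP renders, exact invariance under background
padding. The residual cross-resolution error is pixel quantisation of
single-row widths (worst at the calf, the narrowest site).

## Fat-mass models

Ordinary least squares of reference fat mass on (occupancy, four site
widths), per gender and per target (total, abdominal). OLS is the
minimal family consistent with a slope-1/intercept-0 validation and
makes recovery testable; a ridge penalty (slopes only) is available for
ill-conditioned feature sets. Stature is carried on the feature vector
but enters the design only when `use_stature` is enabled (default off —
the conservative reading of a weight-free model). Body weight is
refused at every entry point: no feature-vector field, a named-column
check in training, and a check on model files.

SEE is the residual SD with n−p−1 denominator. Predictions are floored
at 0.5 kg with a flag — a physical plausibility bound, since a linear
model can extrapolate below zero for extreme lean silhouettes.

For parameter-recovery studies the reference values are synthesised as
an exact linear function of the *measured* features plus Gaussian noise
(`synthesize_reference`). This gives OLS a well-defined generating
truth in feature space: with zero noise, recovery is exact to numerical
precision; with 2.3 kg noise (the error scale such methods report),
coefficient estimates are unbiased within Monte-Carlo resolution. The
coefficients used by the recovery suite come from a deterministic pilot
fit of generated FM on features, pinning the scale to the shape map.

## Agreement statistics

Conventions, fixed once: Lin's CCC uses population (1/n) moments;
Bland–Altman and TEM summaries use the sample (n−1) SD; limits of
agreement are bias ± 1.96·SD of the differences (pred − ref);
proportional bias is the OLS slope of differences on pairwise means
with its two-sided p; all tests are two-sided at α = 0.05 with no
multiplicity correction. Degenerate inputs are handled explicitly:
identical pairs give p = 1 with a degeneracy flag; a zero-variance
difference vector gives a zero proportional-bias slope with p = 1.

"Absolute pure error" has no canonical formula in the 2D-anthropometry
literature; the default here is the group-mean absolute difference
|mean(pred) − mean(ref)| (which matches the magnitude ordering of
published per-gender values), with an RMSE alternative behind
`ape_mode="rmse"`. Neither is asserted as the original definition.

TEM is √(Σd²/2n) over replicate pairs and CV is 100·TEM over the grand
mean — a TEM-based CV, one of two plausible readings of "coefficient of
variation" in reproducibility reporting.

## Pipeline experiments and problem sizes

The validation experiment samples a derivation cohort (default 100
per gender) and an independent validation cohort (84 female, 74 male),
renders and conditions every subject, trains the four models, predicts
the validation cohort and writes per-gender agreement reports; the
reproducibility experiment renders 12 female and 15 male subjects twice
with repositioning jitter and reports TEM/CV/CCC of the replicate
predictions. Cohorts draw from non-overlapping seed streams, so
derivation and validation subjects are disjoint by construction.
Subjects failing QC are excluded and counted rather than fatal.

Default render resolution for the experiments is 2 MP. The features
are resolution-invariant by design (verified separately at 2/5/8 MP),
so the experiment conclusions do not depend on this choice; 2 MP keeps
a full run near a minute. The acceptance script runs both experiments
at these sizes.

**Jitter calibration.** The default `pose_jitter = 1e-4` is an
*output-matched* perturbation scale: it is set so that the end-to-end
replicate variability of predicted FM lands at the few-hundredths-of-a-
kilogram level that repeated-photograph trials of this method class
report. It is not a physical estimate of repositioning magnitude — the
single-row width measurement used here amplifies geometric perturbation
through pixel re-rounding (an error floor of ~0.2 kg SD at 2 MP for
perturbations well below a millimetre), so matching the *output* scale
requires a much smaller input scale than a physical reposition would
suggest. Doubling the jitter above that floor strictly increases TEM.

## Determinism

Every stochastic component takes an integer seed; cohort sampling,
rendering, noise synthesis and the pipeline are pure functions of
(inputs, seed). Pipeline sub-seeds come from a `SeedSequence` spawn of
the run seed. Reports are JSON with sorted keys; a run's manifest lists
every output file with its SHA-256, and re-running the same config and
seed reproduces the files byte for byte (figures included — they are
written without software metadata).

## Known limitations

- The generator emulates silhouette *geometry*, not photography: no
  perspective/parallax, lighting, clothing, hair, or segmentation
  error. Passing tests demonstrate the measurement and statistics
  chain, not robustness to real images.
- The eye line on a featureless mask is a head-height proportion; real
  eye localisation needs image content a binary mask does not have.
  The convention is shared between generator and detector and is
  validated only in that closed world.
- The fat-to-shape map is linear with independent segment noise; real
  torsos covary in ways the map does not represent. Model-recovery
  results say OLS recovers what the generator encodes, not that a
  five-feature linear model suffices for real bodies.
- Metric (cm) reconstruction of body dimensions is out of scope; all
  features are dimensionless.
- Abdominal fat-mass marginals carry the SD shortfall and shape caveat
  described above.
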