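# Methods

`gazecal` estimates a mobile viewer's point of regard (POR) on a large
planar display from two input streams: the 6-DOF head pose **h** =
(h_x, h_y, h_z, h_φ, h_θ, h_ψ) delivered by a motion tracker (cm /
degrees, world frame) and the 2-D pupil centroid **p** = (p_x, p_y) in the
eye camera's image (dimensionless tracker units).  Two estimators are
implemented side by side: a geometric model chain and a Gaussian-process
regressor, together with a session simulator and the calibration-validation
harness used to compare them.

## Coordinate conventions

The world frame is right-handed with its origin at the display centre:
x to the viewer's right, y up, z from the screen toward the viewer, so the
display is the plane z = 0.  Euler angles are intrinsic yaw-pitch-roll:
yaw ψ about the world up axis, pitch θ about the intermediate lateral axis,
roll φ about the body-forward axis (R = R_y(ψ) R_z(θ) R_x(φ)); the
body-forward direction is local +x, and a head facing the display sits at
ψ = 90°.  This choice is deliberate: with the forward axis fixed at (1,0,0)
by the gaze-vector convention below, a yaw-about-z convention would place a
screen-facing head at pitch ±90° — exactly the Euler singularity — and
every simulated pose stream would be degenerate.  With yaw about the up
axis the singularity (pitch ±90°, looking straight up or down) is far from
any realistic operating pose.  At the singularity the canonical branch
ψ = 0 is returned; it is never an error.  Angles are degrees at every
public interface and radians internally.

Motion trackers do not document a single universal convention; only
consistency between the simulator and the estimators matters here, and both
use this one by construction.

## Geometric method

Three models compose:

1. **Head-eye transform** (6 parameters): e = h + R_h·t and R_e = R_h·R_T,
   where t = (x_T, y_T, z_T) is the eye's offset from the tracked marker
   origin in the head frame (cm) and R_T a fixed orientation offset.
2. **Linear eye model** (4 parameters): φ = m_φ p_x + b_φ,
   θ = m_θ p_y + b_θ — slopes in degrees per image unit.  The linearity is
   an approximation (the pupil's image position is a projection of a
   rotating sphere), adequate over the calibrated range and fitted in
   closed form.
3. **Screen model** (centre c, unit normal n, metric size s_x × s_y cm,
   resolution s_u × s_v px): the gaze ray g = R_e R_φ R_θ (1,0,0)^T is
   intersected with the plane and the intersection converted to pixels.
   The pixel frame needs an in-plane "up" completion that a centre+normal
   description leaves free; the world up axis projected into the plane is
   used.  Pixel origin is top-left, u rightward, v downward; coordinates
   are continuous with the panel spanning [0, s_u] × [0, s_v].

The inverse screen mapping — given an eye pose and a target pixel, recover
(φ, θ) — closes the loop for calibration and for the simulator's forward
model.

### Calibration

The calibration cost of a session D = {(x, y)}_n is the mean Euclidean
pixel distance between predicted and true PORs (mean, not sum, so values
are comparable across session lengths; samples whose rays miss the plane
contribute a penalty of twice the screen diagonal).  User calibration
searches the six transform parameters inside a box of ±30 cm / ±45°; for
every candidate transform the four eye-model coefficients are obtained
exactly by regressing the inverse-screen angles of the known targets onto
the pupil coordinates, which removes four dimensions from the nonlinear
search.  The search itself is a bounded Powell direction-set stage followed
by a bounded trust-region least-squares refinement on the per-sample pixel
residuals (finite-difference models; function evaluations only).  The
refinement exists because the transform valley is narrow and strongly
curved — direction-set steps alone zig-zag and leave ~1 px of slack after
thousands of evaluations, while a dozen Gauss-Newton iterations reach the
floor.  Tolerances: objective 1e-6 px (Powell), 1e-12 relative (refinement),
5000 evaluation cap.

Screen calibration wraps the same machinery: the objective at a candidate
screen (centre, two normal angles, optionally metric size — 5 or 7
parameters; resolution from a shape prior; in-plane roll fixed by world-up)
is the sum over users of the per-user minimised cost on a uniform temporal
subset (default 500 samples).  Per-user fits are warm-started across outer
iterations.  A Powell stage is followed by a Gauss-Newton refinement on the
stacked per-user residuals.  Identifiability requires head-orientation
diversity: with a constant head orientation a rigid screen displacement is
absorbed exactly by the head-frame eye offset, so screen calibration is run
on head-free or walking data (where the head-frame offset cannot mimic a
world translation) and, when the physical panel is known, the metric size
can be fixed (`fix_size=True`).

The transform and eye-model parameters are jointly non-identifiable in
general (e.g. a yaw offset in R_T trades against the eye-model intercept
b_φ); recovery is therefore asserted on predictions, never on raw
parameters.

## Gaussian-process method

Two independent zero-mean GPs map the 8-D input (h, p) to u and v
(targets are centred on their training mean, which is added back at
prediction).  The covariance is the ARD kernel

    k(x_i, x_j) = σ_s exp(−½ Σ_d |x_id − x_jd| / l_d),

exponential decay in the length-scale-weighted absolute per-dimension
distance — a product of Laplacian kernels, positive definite.  A
squared-exponential variant exp(−½ Σ (Δ_d/l_d)²) is available via
`kernel_form="squared"` since the absolute-distance form may plausibly be
intended as squared; the absolute form is the default.  The training
covariance is K_ij = k(x_i, x_j) + σ_n² δ_ij; prediction uses the standard
conditioning formulas μ* = K*K⁻¹y and Σ* = K** − K*K⁻¹K*ᵀ via a Cholesky
factorisation with adaptive jitter (1e-10 ×10 up to 1e-4).  The predictive
standard deviation (pixels) is the per-sample confidence score.

Hyperparameters Θ = (σ_s, σ_n, l_1..l_8) are fitted by maximising the
marginal log-likelihood, optimised in log space with analytic gradients
(L-BFGS-B), constrained to (0, e^10].  The first start is the all-ones
configuration.  In raw tracker units the input dimensions span four orders
of magnitude (pupil coordinates in the thousands, positions in the tens),
and at unit length scales the kernel underflows to a diagonal: the
likelihood gradient is numerically zero and no optimiser can leave that
start.  A second start is therefore placed at the data scale — per-dimension
median absolute differences times a multiplier chosen by the likelihood
from {1, 3, 10, 30}, with moment-matched signal/noise variances — and the
final Θ is whichever start attains the higher likelihood.  The result is
never worse than the all-ones optimisation alone.  No input standardisation
is applied by default (the ARD length scales absorb scale).

Hyperparameters are fitted on a uniform temporal subset (default 500
samples); the kernel matrices are then built on the full calibration set
capped at 2000 samples.  K⁻¹y is precomputed, so repeated mean-only
prediction is a dot product per query.

## Session simulator

The simulator generates the two stimulus protocols used for calibration
and validation:

* **Dynamic pursuit** (3 min): a marker moving at 100 px/s along cardinal
  directions, segments ≥ 100 px, 750 ms pause at every direction change
  (the new direction is drawn uniformly from the three other cardinal
  directions with room for a full segment), all within the panel.  State
  changes at sample boundaries, so in-motion steps are exactly 100/rate px.
  Where the pursuit begins and its first direction are not constrained;
  both are drawn uniformly.
* **Static grid** (5 min): 20 points of a 5 × 4 grid spanning ±32° × ±23°
  of visual angle from the chin-rest position (140 cm, on axis), each shown
  10 times for 1500 ms in 10 random permutations of the grid — 200
  presentations.

Head motion comes in three mobility conditions.  *head_fixed*: constant
chin-rest pose.  *head_free*: fixed position, orientation wandering around
facing the current stimulus.  *walking*: position wandering inside the
150 × 145 cm floor area in front of the display.  Real sessions get their
motion from a human and no motion model is prescribed by the protocol; the
simulator uses Ornstein-Uhlenbeck processes, chosen once as realistic —
yaw sd 4°, pitch sd 2.5°, roll sd 1.5° around the stimulus-facing
orientation with 2-3 s time constants, and for walking a 2-D OU wander
(sd ≈ 31 cm after tanh-squashing that keeps positions strictly inside the
area) with a 5 s time constant at a fixed eye height.

The forward model assumes exact fixation of the stimulus: the ground-truth
transform gives the eye pose, the inverse screen mapping the required
angles, and the inverted linear eye model the pupil centroid.  Gaussian
sensor noise is then applied to the *recorded* streams — pupil noise in
image units, head position/orientation noise on the recorded pose only (the
pupil is generated from the true pose, as on real hardware).  Defaults:
pupil 15 units (≈ 0.15° through the default 0.01 °/unit eye model), head
0.05 cm / 0.1° — video-tracker-class precision.  Optional fixation jitter
(degrees) relaxes the exact-fixation assumption.  The default ground truth
places the eye 8 cm forward of and 9 cm below the tracked marker centroid
(markers sit on the helmet above the eyes) with no orientation offset.

At zero noise the forward model and the geometric predictor are exact
inverses — the basis of the inverse-consistency suite.  What passing these
tests does *not* show: robustness to the nonlinearities of real pupil
images, helmet slippage and drift, blinks, or imperfect fixation — none of
which the simulator emulates.

## Evaluation harness

Sessions are split per the standard protocol: dynamic phase → first 2 min
(Calib-Dynamic) / last minute (Valid-Dynamic); static phase → stable
fixations only, first 2 min (Calib-Static) / last 3 min (Valid-Static).
The fixation filter drops the first 1250 ms after each static stimulus
onset, keeping the final 250 ms (15 samples at 60 Hz).  Calibration never
uses Calib-Static alone — discrete fixations lack the head/eye variability
a regression needs.

Errors are reported in degrees of visual angle: both PORs are lifted to
world points and compared as direction vectors from the current head
position.  The combined error is the angle between the vectors
(frame-independent, the primary metric); azimuth/elevation are signed
differences of world-frame spherical coordinates (the decomposition frame
is a convention — the combined error does not depend on it).  Session
summaries are arithmetic means over validation samples.

The overlap statistic bins the 5-D space of head position (10 cm bins) and
pupil position (1500 image-unit bins; configurable, since pupil units
differ across trackers) with half-open intervals anchored at the origin,
and reports |bins visited by both| / |bins visited by validation| ∈ [0, 1].
Head orientation is excluded to keep the space densely populated.  An
alternative denominator (bins visited *exclusively* by validation) is
available behind a flag but can exceed 1; the bounded reading is the
default.  Predictions whose mean predictive SD is ≥ 75 px (default) can be
rejected, and the rejected fraction is always reported.

## Problem sizes and numerical defaults

The recovery experiments shipped with the package use dynamic-phase
sessions at 60 Hz (10 800 samples), calibration subsets of 300-500 samples,
GP kernel matrices of 1200-1500 samples and validation subsets of
1200-2000 samples; screen recovery uses 150-sample subsets.  These sizes
hold the full recovery suite to about a minute of compute while leaving the
measured quantities far inside their tolerances (geometric recovery ≈ 0°,
GP recovery ≈ 1°, screen centre to < 0.01 cm on noiseless data).  The
single unified sample rate replaces the mixed 250/60 Hz of real hardware;
both estimators are rate-agnostic and `align_streams` handles mixed-rate
real recordings by linear (positions, pupil) and shortest-arc spherical
(orientation) interpolation onto the faster stream.

## Known limitations

* The linear eye model ignores projection nonlinearities at large
  eccentricities; a spherical-projection eye model is a known refinement
  and is out of scope here.
* No drift/slippage correction between calibration and test.
* The GP pair is two independent processes; cross-covariance between u and
  v is not modelled.
* Exact kernel GP only: training is O(n³), hence the 2000-sample cap.
* The simulator's motion model is statistically plausible, not
  biomechanical; gait, VOR dynamics and saccade kinematics are not
  simulated.
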