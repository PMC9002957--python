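# Methods

`mvkin` implements a markerless-kinematics pipeline — multi-camera
triangulation of 2D joint keypoints, low-pass filtering, constrained
skeletal inverse kinematics — together with the concurrent-validation
statistics used to compare it against a marker-based protocol, and a
virtual-camera gait simulator that makes every stage testable against exact
ground truth. This note records the models, the defaults and why they were
chosen, the numerical decisions, and the limits of what the synthetic
validation shows.

## Coordinate conventions

World frame: right-handed, +X the progression direction, +Y up, +Z the
subject's right; meters. All public interfaces use degrees; rotations are
applied in radians internally. Cameras follow the pinhole model
`x_c = R X + t`, `u = fx x/z + cx`, `v = fy y/z + cy`, with no distortion
(the virtual cameras are ideal; real-camera calibration is out of scope).

## Triangulation

The weighted Direct Linear Transform stacks, per camera, the two rows
`c·(u·P₃ − P₁)` and `c·(v·P₃ − P₂)` of the homogeneous system (P the 3×4
projection matrix, c the keypoint confidence) and takes the right singular
vector of the smallest singular value. Linear row weighting is the simplest
scheme consistent with a confidence-weighted DLT; a squared-confidence
variant would only change the relative influence of mid-confidence views.
Observations at or below `min_confidence = 0.3` are excluded — occluded
detections carry confidence 0 and near-zero detections are uninformative.

The robust loop re-solves while the mean reprojection residual exceeds
`max_reproj_error = 15 px` and more than two cameras remain, each round
dropping the camera with the largest residual (ties: lower confidence
first, then lower camera index, so the procedure is deterministic). On a
1000 px virtual image with ~2 px detection noise, 15 px separates the noise
regime from gross mislocalizations by an order of magnitude; both
parameters are config-exposed. If even the final two cameras violate the
threshold, the best two-camera solution is returned flagged low-quality
rather than dropped, so downstream stages can decide. Interior invalid
runs up to `max_gap = 5` frames are bridged by linear interpolation;
longer gaps stay invalid.

## Filtering, events, normalization

The default low-pass is a zero-phase (forward–backward) Butterworth,
4th-order per pass, 6 Hz cutoff at 30 Hz sampling. Zero-lag filtering is
standard practice here because the downstream agreement statistics are
phase-sensitive; a single-pass variant is selectable. The dual pass squares
the magnitude response, so the design cutoff is pre-warped until the
cascade is exactly −3 dB at the nominal cutoff; the analog correction
factor `(√2−1)^(−1/(2n))` is refined by root-finding on the actual digital
(bilinear) response, which matters because 6 Hz is a sizeable fraction of
the 15 Hz Nyquist rate. Gait harmonics (≤ 3 × cadence ≈ 3 Hz) pass
essentially unattenuated: a 1 Hz ±30° sinusoid keeps its peak within 1%,
while a 12 Hz component is attenuated by more than 95%.

Heel strikes are coordinate-based events: local maxima of
`direction × (heel − sacrum)` along the progression axis. The per-frame
direction is the sign of the smoothed sacrum velocity, which handles
back-and-forth trials; subjects whose total excursion is below 0.5 m are
treated as stationary. The minimum peak separation is half the nominal
stride time (the stride time is known from the metronome cadence), which
rejects double peaks from noise. Pedaling has no heel strikes; cycles are
segmented at the peaks of the ankle's vertical position, a crank-angle
proxy. Each cycle is linearly time-warped to 101 samples (0–100%, the
field's conventional grid; config-exposed).

Resampling is Fourier-based (band-limited), appropriate for the
near-periodic signals this package handles; edge behavior on aperiodic
signals is the usual FFT wrap-around caveat.

## Skeletal model and inverse kinematics

The shipped model is a simplified full-body humanoid sized for a ~1.8 m
adult: pelvis root, a five-vertebra lumbar stack, torso, head, and
thigh–shank–foot / upper-arm–forearm–hand chains per side. It is not an
anatomical asset; it exists to reproduce the *constraint structure* of the
constrained-IK protocol exactly:

* wrist flexion and deviation locked at 0°, forearm pronation/supination
  locked at 90° (no keypoint informs them);
* pelvis translation and the subtalar angle unlocked;
* hip flexion limited to 150° (120° is not enough for pedaling);
* knee abduction/adduction and internal/external rotation coupled to knee
  flexion. The coupling curves are piecewise-linear, zero at zero flexion,
  with default knots (0, 90, 150)° → (0, 3, 4)° and (0, 8, 12)°; the true
  spline of any particular anatomical model can be loaded from config;
* each lumbar vertebra carries one fifth of the total lumbar flexion
  (printed ratios for the vertebral distribution are not available, equal
  sharing is the neutral choice).

21 keypoints are placed on the model (the BODY_25B dialect minus eyes and
ears): joint-center keypoints sit at their segment origins; heel, toes,
head and nose carry local offsets. Keypoint weights follow the protocol:
1 everywhere, 0.1 for Nose/Head, 2 for Shoulders/Hips. A config-supplied
per-keypoint offset table can shift placements on the unscaled model to
compensate measured detector biases; the default is zeros.

**Scaling** is measurement-based: each segment group's factor is the ratio
of experimental to model distance for its keypoint pair (thigh:
hip–knee; shank: knee–ankle; foot: heel–big-toe; arms likewise). The
pelvis and lumbar/torso stack share the vertical mid-hip→neck measurement:
hip-to-hip width is exactly the quantity that detector biases corrupt, and
an inflated pelvis height opens a lordotic-vs-kyphotic spine ambiguity
that leaks tens of degrees into hip flexion (the same double-solution
pathology that shows up as a hip offset in real captures).

**IK** solves, per frame, a bounded nonlinear least squares over the free
coordinates: locked and coupled DOFs are substituted before optimization
(hence exact to machine precision), limits become box bounds (the
trust-region-reflective solver keeps iterates strictly feasible).
Zero-angle priors (weight 1 on pelvis list, pelvis tilt, lumbar flexion
and the ankle angles, in radians) apply only to the static scaling solve,
where the subject is known to stand upright with flat feet; dynamic frames
use keypoint terms only. Frame 0 starts from the neutral pose and each
subsequent frame warm-starts from the previous solution, which keeps the
solution branch continuous on band-limited motion. Convergence tolerance
is 1e-8 on the objective with at most 200 iterations (config-exposed);
Jacobians are one-sided finite differences evaluated as a single batched
forward-kinematics pass, which is what makes per-frame solves take tens of
milliseconds. The reported per-frame marker RMSE is the unweighted RMS of
model-to-experimental distances, because the 2–4 cm best-practice bound it
is compared against refers to that quantity; weights act only inside the
objective.

The functional hip center uses the algebraic (Coope) least-squares sphere
fit per marker, expressed in the pelvis frame, averaging per-marker
centers. Near-zero singular values of the design matrix expose degenerate
motion: planar arcs leave the out-of-plane coordinate flagged
low-confidence, and static or purely translated markers raise an error.

`direct_segment_angles` is the deliberately naive baseline: hip flexion as
the trunk-axis-to-thigh-vector angle, knee as thigh-to-shank, ankle as
shank-to-foot, all projected on the sagittal plane. Systematic keypoint
offsets pass into these angles undamped — this is the comparator for the
claim that a constrained model mitigates detector bias.

## The simulator

The simulator defines the study conditions: an 8-camera virtual rig
(radius 4 m, 900 px focal length, 1000×1000 px, aimed at the subject),
30 Hz sampling, and a metronome-paced subject. Joint-angle trajectories
are sums of at most three harmonics of the cadence with task-specific
amplitude tables (walking: 1 Hz cadence, 1.3 m stride, hip 10° ± 25°, knee
33° ∓ 27° with a second harmonic, ankle ±12°; running: 1.3 Hz, larger
amplitudes; pedaling: stationary pelvis, hip 65° ± 20°, knee 75° ± 35°).
Amplitudes are conservative textbook-order values. A slow seeded amplitude
modulation (2% via two incommensurate sub-cadence sinusoids) makes
consecutive cycles similar but not identical, as in real gait, while
keeping trajectories smooth and band-limited below the 6 Hz cutoff.

Walking and running are back-and-forth (2 cycles per pass by default):
a single 8-cycle pass would leave the camera volume. Turns are smooth
(cosine velocity ramp plus 180° yaw over half a cycle) and centered
mid-swing so heel strikes stay clean; the generating cycle boundaries are
the ground-truth events, and the first strike is placed a tenth of a cycle
into the trial so no event sits on the signal boundary.

Observations are corrupted in the order: systematic 3D offset →
projection → Gaussian pixel noise. Systematic offsets are constant per
keypoint (bounded at 0.1 m) and expressed, by default, in the frame of the
keypoint's *proximal* segment — a detector mislocalizes the hip relative
to the pelvis, not relative to the swinging thigh — with a world-fixed
option for analyses that need a time-constant world bias. The offset
sampler draws one direction per right-side joint and mirrors it to the
left (detector biases are subject-independent and bilaterally symmetric),
with magnitudes uniform in 3–5 cm for hip/knee studies. Confidence is
`clamp(1 − pixel_error/20 px, 0, 1)` for visible keypoints and 0 when
occluded or out of view — monotone, bounded, and invertible for tests.

The reference channel emits anatomical-marker trajectories: malleoli,
femoral epicondyles and styloid pairs whose midpoints equal the true joint
centers exactly before noise, a sacrum marker, heel/toe markers, and
four-marker thigh clusters for the functional hip method. Soft tissue is
modeled as i.i.d. Gaussian noise only (no correlated skin-motion
artifact). The marker-based protocol is reproduced at desk scale: joint
centers from midpoints, hip centers from the sphere fit, IK on the same
skeletal model with weights 5 (joint centers) / 2 (anatomical markers).

## Agreement statistics

The inter-protocol CMC is the variance ratio

    CMC = √(1 − [Σ (Y_pgf − Ȳ_gf)² / (G·F·(P−1))] / [Σ (Y_pgf − Ȳ_g)² / (G·(P·F−1))])

with Ȳ_gf the between-protocol mean at frame f of cycle g and Ȳ_g the
cycle's grand mean. The normalization constants are unit-tested against a
brute-force triple-loop evaluation. A negative radicand (offset exceeding
the grand mean ROM) is reported as NaN and classified "none"; bands are
≥0.95 excellent, 0.85–0.94 very good, 0.75–0.84 good, else poor. Identical
constant curves return 1 by convention, with a warning.

ROM error uses per-cycle max−min differences; normality is checked with
Shapiro–Wilk before the paired t-test (reported but flagged when
non-normal). Bland–Altman pools differences over all cycles and frames;
LoA = bias ± 1.96 sd; the normality check preceding the bias test is run
on the *per-cycle mean* differences (the pairing unit is ambiguous in
common usage; per-cycle means are the conservative reading and the choice
is config-visible). Heteroscedasticity is flagged when |d| correlates with
the paired means at α = 0.05; all significance thresholds are 0.05.
`RMSE² = bias² + Var(d)` holds as an algebraic identity and is tested.

## What the synthetic validation shows — and does not

Passing tests show that the pipeline is an exact inverse of the simulator
in the noiseless limit, that its accuracy degrades gracefully under pixel
noise, occlusion and systematic offsets, and that the constrained model
mitigates joint-center bias relative to direct segment-vector angles
(aggregated over 20 seeds at 3–5 cm hip/knee offsets). They do not show
performance on real images: the simulator has ideal calibration, pinhole
optics, harmonic kinematics, i.i.d. soft tissue, and offsets that are
constant in a body frame. Real detector errors are pose-dependent,
calibration is imperfect, and spine/pelvis indeterminacies are worse with
sparse keypoints. Problem sizes (8–13 cycles, 30 Hz, 60–240 frames per
trial, 20-seed replications) were chosen to match the study conditions
while keeping a full validation run in minutes on one CPU.

## Known limitations

* The skeletal model's dimensions and coupling knots are schematic
  defaults, not anatomical estimates; load a config to replace them.
* Single subject per scene; no multi-person association.
* No RANSAC triangulation, no Kalman smoothing, no dynamics, muscles or
  ground-reaction modeling; no real-time mode.
* The cycling event rule (ankle-height peaks) is a proxy; crank data would
  be better if available.
* TRC/MOT interop only; no binary capture formats.
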