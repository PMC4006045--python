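# Methods

## Kinematic model

The arm is a serial chain — torso (carrying the scapula sensor), upper
arm, forearm, hand — with three rotational degrees of freedom at shoulder,
elbow and wrist (nine in total). World coordinates are right-handed,
meters, vertical = +Z; quaternions are scalar-first and unit norm.
Anatomical segment frames follow the biomechanical convention: y along the
segment pointing proximally, z mediolateral, x anterior; at zero joint
angles the arm hangs straight down. Each joint's rotation is an intrinsic
Z-X-Y Cardan sequence read as flexion/extension, adduction/abduction,
internal/external rotation, in degrees. The standard references for joint
coordinate systems leave the exact axis constructions to the implementer;
the constructions used here are:

* **torso**: z along c7 → acromion, x-hint c7 → suprasternale;
* **upper arm**: y along elbow → shoulder center, z-hint along the
  epicondyle line;
* **forearm**: y along wrist → elbow center, z-hint along the styloid
  line;
* **hand**: y along metacarpal midpoint → wrist center, z-hint along the
  MC2–MC5 line.

Because loading *signs* depend on these conventions, every similarity
statistic downstream uses |Pearson r|, which is convention-robust.

## Calibration (CAST stage)

Stylus records give each landmark's offset in its adjacent sensor frame
(`offset = R(q)⁻¹ (x_global − p_sensor)`). The glenohumeral center is
found by expressing the upper-arm sensor origin in the scapula-sensor
frame during a circumduction and sphere-fitting the cloud: algebraic
(Kåsa) initialization from the linear normal equations, refined by
Gauss–Newton on the geometric residual Σ(‖pᵢ−c‖−r)², tolerance 1e-10, at
most 100 iterations. Degeneracy (planar arcs) is detected by the smallest
singular value of the centered cloud falling below 1e-8 of the largest.
Elbow and wrist centers are epicondyle and styloid midpoints. The core's
striking surface is a total-least-squares plane through ≥ 3 stylus points;
the hammer working point is a stylus record in the hand-sensor frame.

## Reconstruction and segment-length optimization

Per frame, every calibrated point is mapped through its sensor pose.
Soft-tissue artifact appears as time-varying inter-center distances;
reference segment lengths are the mean distances over a sedentary window
(default: the first 2 s of each trial, which the generator guarantees to
be quiet) and are imposed by a proximal-to-distal sweep that re-places
each distal center on the ray from its corrected proximal center at
exactly the reference length. The sweep is idempotent and leaves
inter-center distances exactly constant. Angles come from the relative
orientation of adjacent anatomical frames, unwrapped per channel; frames
with a second (add/abd) angle within 1° of ±90° are flagged as
gimbal-adjacent rather than rejected.

## Strike segmentation

Candidate impacts are local minima of the vertical hand-sensor trace whose
hammer working point lies within 5 cm (configurable) of the registered
surface plane and whose descent from the window maximum exceeds 5 cm
(rejecting micro-minima while the hammer hovers after a blow). The start
is the sensor's highest vertical position since the previous movement
ended; the end is the earlier of the segment's lowest point and the first
below-threshold speed frame *after the movement's speed peak* — "slowed
below" presupposes having been fast, and at the apex itself the sensor is
momentarily at rest, so an unconditional first-crossing rule would end
every segment immediately. The printed threshold value 4.17 × 10⁻³ equals
the 240 Hz frame interval in seconds read on the m/s scale; this unit
oddity is preserved as conventional and fully overridable. Speeds are
central differences with one-sided ends and no smoothing.

## Energetics

`Ek_max = ½ m v_max²` with `v_max` the peak working-point speed over the
segment (the apex-to-impact window is the natural maximal window);
`Ep = m g h` with `h` the vertical (gravity-axis, not plane-normal)
distance from the working point at the start frame to the surface plane,
`g = 9.81 m/s²`. `Ek/Ep` is undefined (and excluded from summaries) when
`Ep ≤ 0`. At 240 Hz, central differences under-read a sharp bell-shaped
speed peak by up to ~0.7% (≈1.4% on Ek after squaring); the gravity-drop
oracle trials are grid-aligned by construction and recover the ratio
exactly.

## Task performance

Flake statistics use the n−1 SD (defined as 0 for a single flake) and
`CV = SD/mean × 100`. Group CV is the mean of per-subject CVs. Inference
is Welch (unequal-variance) t-tests over all six pairs of the four groups
at `α = 0.05/6`; one-sided (decreasing with expertise) for CV, two-sided
for the energy measures. Skill allocation is an explicit rule set over
small- and large-flake outcome statistics: a size is "met" when the median
mass lies within ×/÷ 2 of the model mass (12 g small, 50 g large);
neither met → uninitiated, one met → novice, both met → intermediate,
promoted to expert when the pooled CV ≤ 65%. The published allocation was
qualitative; these defaults make it explicit and reproducible, and every
decision returns its full rule trace.

## Per-strike PCA

The 9 × 9 covariance matrix (not correlation — all channels share degree
units, and the covariation structure is the object of interest; a
correlation-matrix switch exists) of the joint-angle channels over the
segment frames is eigendecomposed; eigenvalues are sorted descending,
loadings sign-normalized (largest-magnitude element positive). No time
normalization is applied: loadings are length-9 and comparable across
strikes of different durations. Consistency of coordination requires
|r| > 0.7 in *all* pairwise PC1-loading comparisons of a subject's
successful strikes.

## The synthetic rig

The generator is the package's study-condition definition, not a tuning
dial. Defaults: four groups of 6/6/3/4 subjects; per-strike energy targets
drawn from the published group profiles (Ek means 12.30/4.20/5.21/4.44 J,
SD 4.88/1.27/2.36/2.56; Ep means 3.39/2.24/2.13/1.37 J), truncated to the
arm's reachable workspace (Ep ∈ [0.7, 5.0] J — below 0.7 J the apex would
sit inside the 8 cm rest clearance above the core, above 5.0 J outside
reach); strike economy from the published strikes-per-flake averages
(2.2/1.6/1.3/1.4) via a per-strike success probability under the
three-strike rule; 600 g hammer; 240 Hz sampling.

Each strike is a minimum-jerk joint-space movement along a per-strike
synergy direction: rest → apex posture (solved so the working point sits
`Ep/(m g)` above the surface) → surface contact, with the descent duration
solved by the exact 1/T speed scaling of a fixed geometric path so the
peak working-point speed meets the Ek target. Per-strike directions are
jittered around a per-subject template but constrained to be
kinematically plausible for a blow (hand and hammer must descend
together); secondary joint-space components — giving each strike its
multi-component covariance with group-specific PC1/PC2/PC3 shares
(0.64/0.20/0.16 uninitiated … 0.76/0.16/0.08 expert, mirroring the
published joint-angle variation structure) — are slow bumps projected into
the task null space (orthogonal to the primary direction and to the
working-point and hand height gradients along the path), i.e. elemental
joint variability that leaves the hammer's vertical trajectory first-order
invariant: variable joints, stable working point. A validation loop
shrinks the secondary amplitude if the realized path would touch the
surface early or rise above its apex, so every generated strike is
well-formed. Ground truth (apex height, Ep, densely-sampled peak speed,
Ek) is measured from the *realized* trajectory, so the ledger is exact
regardless of frame rounding.

Measurement error: soft-tissue artifact is 0.5–3 Hz sinusoidal sensor
displacement in the segment frame, amplitude 4 mm scaled per site (1.0
upper arm, 0.7 forearm, 0.4 scapula, 0.25 hand dorsum) and dominated by
the segment's long axis (skin slides along the limb; transverse amplitude
a quarter of longitudinal) — which is exactly why inter-joint distances
are the visible symptom and why length enforcement recovers accuracy —
plus 0.1 mm white position noise (electromagnetic trackers are sub-mm
devices). Orientation streams are noise-free; this idealization is listed
under limitations.

Flake masses: `mass = median_g · f(Ek)/f(Ēk) · exp(σ_b Z_subject + σ_w Z)`
with `f(E) = E/(E+2 J)` a saturating monotone response, a persistent
per-subject lognormal style factor (σ_b) and within-subject lognormal
noise (σ_w). Medians and sigmas are calibrated to the published group
medians (3.5/10/8/12 g in the analyzed condition; the expert median equals
the 12 g model flake) and group SDs (65.1/30.5/23.7/19.7 g), with σ_w set
from the published per-subject average CVs. Gravity-drop oracle trials
freeze the joint angles at the apex and translate the whole body in free
fall, with the surface crossing placed exactly on the sample grid and one
extra free-fall frame past it, so 240 Hz central differences recover
`v = √(2gh)` — and the Ek/Ep ratio of 1 — to float precision.

## Problem sizes and replicate studies

The default cohort is analyzed at full scale (19 subjects, ~80–95 strikes,
~25 s on one CPU). The two Monte-Carlo replicate studies are sized by
design-stage power analysis: group-difference significance is replicated
at the study's own per-group strike counts (33/28/12/16, where the Welch
statistics are ≈ 7–9 and power is essentially 1), while the flake-mass
SD-ordering study uses 30 subjects per group, because at 3–6 subjects per
group the sample SD of a heavy-tailed mass distribution carries almost no
ordering information (the original report itself notes the power limit of
its sample sizes). Even at that size, the four-way sample-SD ordering is
recovered in only ~11% of replicates under this calibration: the sample SD
of a lognormal with σ ≈ 1.3–1.7 has a relative standard error near 1 at
these n. The replicate study reports the measured fraction rather than
hiding it; a stable dispersion ordering would require either far lighter
tails than the published dispersions imply or orders of magnitude more
flakes.

## Known limitations

* The generator's strike template is minimum-jerk with a task-null
  secondary structure; real strikes have richer intra-movement dynamics
  (impact transients, deceleration before contact), none of which the
  analysis depends on.
* Orientation measurement error and sensor-mount slippage are not
  simulated; soft-tissue artifact is positional only.
* The skill-allocation rule set is an explicit operationalization of a
  qualitative published procedure; on synthetic cohorts it agrees with
  the generating group only moderately (the mass distributions of adjacent
  groups overlap heavily, as in the real data).
* Passing recovery tests on the rig shows the pipeline inverts its own
  generative model under realistic noise; it cannot certify performance on
  real electromagnetic-tracker data with marker slippage, metal
  interference, or non-rigid torso motion.
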