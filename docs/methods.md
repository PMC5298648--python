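# Methods

## Model and assumptions

The body is 16 rigid segments (head, upper/middle trunk, pelvis, and
left/right upper arm, forearm, hand, upper leg, lower leg, foot).  Inertial
parameters come from the adjusted Zatsiorsky–Seluyanov table (De Leva 1996)
shipped as package data: mass fraction of net body mass, CoM position and
radii of gyration as fractions of segment length.  Segment frames are
right-handed with the longitudinal axis `z` running proximal → distal and the
CoM offset applied along it; the table's single longitudinal CoM column means
non-longitudinal offsets are taken as zero for all segments, including trunk
and pelvis.  Inertia tensors are diagonal in the segment frame,
`J_kk = m (r_k L)²`, and rotated per sample into the global frame.

Worn instrumentation is handled literally: its total mass is subtracted from
the measured mass before the fractions are applied, each component is added
back to its carrier segment, and the resulting segment mass (net-derived plus
instrumentation) feeds the radius-of-gyration inertia while the radii
themselves are unchanged.  The default hardware map places the sternum and
shoulder units plus pack and battery on the upper trunk (0.250 kg) and one
10 g unit on each remaining instrumented segment, 0.390 kg in total.

The central dynamic assumption is that ground contact is the only significant
external load, so internal joint forces cancel over the closed chain and the
total external wrench about a point O is the gravito-inertial sum given in the
README.  Per-joint end-point force terms are therefore never evaluated
individually; the formulation is algebraically identical for a free body.
Systems that merge a finer segmentation into these 16 segments can use
`merge` conventions upstream; the dynamics core is vendor-agnostic and takes
16-segment kinematics as canonical input.

A second assumption is a straight overground walk: the walking frame differs
from the global frame only by a yaw rotation, fixed from the initial and
final pelvis positions (error below 0.5 m of horizontal displacement).

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `cutoff_hz` | 6.0 | Hz | zero-phase 2nd-order Butterworth on a, ω, ω̇ |
| `filter_order` | 2 | – | per-pass order (forward+backward ⇒ 4th-order magnitude) |
| `heel_multiplier` | 0.6 | – | heel-strike threshold as a fraction of v_th |
| `toe_multiplier` | 1.9 | – | toe-off threshold as a fraction of v_th |
| `min_gap_s` | 0.05 | s | refractory period suppressing threshold chatter |
| `fz_threshold_n` | 5.0 | N | COP validity / force-plate event threshold |
| `gravity` | 9.81 | m/s² | shared by dynamics and BW normalisation |
| `n_points` | 101 | – | percent-of-gait-cycle grid (0–100 % inclusive) |

Filtering interpretation: "second-order zero-phase" is implemented as a
2nd-order design applied forward and backward (`filtfilt`), the standard
biomechanics reading.  Angular acceleration, when absent, is obtained by
central finite differences *before* filtering, because differentiation
injects high-frequency content that the filter is there to remove.  Provided
point velocities are used as-is for event detection; velocities derived by
differentiating positions are filtered like the other dynamic channels.

Event semantics: an event is assigned to the first *sample* satisfying its
strict inequality (no sub-sample interpolation); the state machine starts in
stance iff the first heel-speed sample is already below threshold, a choice
that is logged.  The heel-strike condition uses a falling crossing and the
toe-off a rising one — the foot decelerates into contact and the toe
accelerates into swing.

Moment bookkeeping: during single support the total wrench is re-expressed
about the stance foot's ankle-joint ground projection, recomputed every
sample.  During double support the total is expressed about the trailing
foot's projection; the trailing wrench is the anchor value at the leading
heel strike scaled componentwise by the transition curves, and the leading
wrench is the remainder, transferred to its own projection.  Because the
leading side is defined by subtraction about a common point, the force and
moment balances hold to machine precision whatever curves are used.

## Smooth-transition curves

The six shape curves (three force, three moment components, walking frame)
are tabulated knots with a cubic-spline interpolant, pinned to f(0)=1 and
f(1)=0.  The package default is the raised cosine `f(τ) = (1 + cos πτ)/2`
for all six components: it satisfies the boundary conditions with zero end
slopes, is monotone, and serves as a neutral, fully documented stand-in for
empirically calibrated curves.  `calibrate_sta` is the intended production
path: trailing-foot curves from every double-support episode of a force-plate
corpus are normalized by their value at the leading heel strike, resampled on
τ ∈ [0, 1], averaged, endpoint-clamped and splined.  Episodes with a
vanishing anchor component are excluded (warning), since normalization is
then ill-posed.  A known limitation inherited from single-curve transition
models: using one curve family for both horizontal moments and vertical force
constrains how the COP can evolve during double support, so COP behaviour
there is exposed as a diagnostic rather than asserted.

## Synthetic gait generator

The generator emulates a normal-speed walk (defaults: 1.28 m/s, 1.1 s
stride, 12 % double-support fraction per side, 240 Hz, 77.34 kg / 1.81 m
subject with the 0.390 kg hardware map — the reference study conditions).
Design choices that make it an exact oracle:

- Segments translate with an analytic whole-body CoM path whose second
  derivative reproduces the prescribed total force; orientations are
  constant.  Limb swing is antisymmetric within equal-mass left/right pairs,
  leaving the total force exact; the single surviving cross term (pair
  separation × swing acceleration) is added to the ground-truth transverse
  moment in closed form.  Rotational Euler terms are exercised separately by
  an analytic three-link pendulum whose linear and angular momenta have
  closed forms, so external-wrench code can be checked against momentum
  derivatives — an independent route that never touches the Newton–Euler
  summation.
- The total force is body weight plus sinusoids: vertical at step frequency
  (±15 % BW), anterior at step frequency (15 % BW, phase −π/4 so heel
  strikes land on a propulsive value), lateral at stride frequency (4 % BW,
  phase +π/3).  The phase offsets keep the trailing-foot anchors away from
  zero at every heel strike; without them the smooth-transition
  normalization would be degenerate by construction.
- Event times are integer sample counts.  Heel/toe speeds are trapezoids
  whose threshold crossings are placed half a sample before each event, so
  the first-sample rule lands exactly on the ground-truth sample and stays
  there under the small v_th jitter introduced by sampling the pelvis
  velocity.
- Per-foot ground truth applies the gait-phase distribution table to the
  analytic total with the spec'd curves, in code independent of the
  production `distribute` path.
- Optional white Gaussian noise goes on linear-acceleration and
  angular-velocity channels only (positions stay clean), an IMU-like error
  structure; one seeded generator makes trials bit-reproducible.

What the generator does **not** emulate: soft-tissue artifact, magnetic
disturbance, orientation-estimation drift, non-straight walking, double
support produced by actual foot-ground contact mechanics, or physiological
joint kinematics (the heel/toe/ankle point trajectories are kinematically
plausible but not rigidly bound to the translating foot segment — binding
them would forfeit the closed-form wrench, which is the property the tests
need).  Passing the synthetic suite therefore demonstrates correctness of
the implementation, not field accuracy on real inertial-capture data.

## Numerical choices

- Conservation is enforced structurally (leading foot by subtraction), not
  numerically; residuals are pure round-off (~1e-12 N at body-weight scale).
- The anchor for the trailing-foot scaling is the value at the event sample;
  τ uses the actual event-bounded interval per episode.
- A zero-length double-support interval raises a degenerate-phase error.
- Both feet in stance with no bounding episode (standing) splits the wrench
  50/50 about the two ankle projections; normal gait never reaches this.
- rRMSE is undefined (NaN + warning) when both curves are flat; Pearson
  correlation likewise for constant curves; Sprague–Geers raises on
  zero-energy input.  Correlation bands are inclusive on the upper edge
  (ρ = 0.35 is "weak", ρ = 0.9 "strong").
- Full-cycle metrics are computed per gait cycle on the 101-point grid and
  averaged with SD across cycles; sub-phase slices pool samples.
- Evaluation problem sizes: 6-stride trials (~1700 samples) for pipeline
  checks and a 26-stride trial (53 double-support episodes) for calibration
  recovery — small enough to run in seconds yet several times longer than a
  single gait cycle.

## Known limitations

- Default transition curves are a neutral analytic family, not empirically
  calibrated ones; accuracy on real data hinges on `calibrate_sta` with a
  representative corpus, and curves calibrated on healthy adults will not
  transfer to pathological gait.
- Valid for walking only: the distribution table assumes alternating single
  and double support, and the double-support computation needs the full
  phase, so per-foot output is not real-time during double support.
- Event thresholds were designed for normal-range walking speeds; very slow
  or very fast gait may need re-tuned multipliers.
- Anthropometric ratios are population averages; no subject-specific inertia
  personalisation is provided.
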