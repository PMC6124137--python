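# Methods

This note documents the models and procedures implemented in
`fightkit`, the assumptions behind them, the parameters that matter,
and the design choices made where the design was genuinely open.

## Coordinates, motion derivation

All positions are centroids in cm with the origin at the arena's
bottom-left corner, x right, y up; frames are 0-based and time is
`frame / frame_rate` (default 20 Hz).  One fixed convention avoids
sign errors in the turning maps, where "right of the fish" matters.

Velocity and acceleration are central differences,
`v_t = (x_{t+1} − x_{t−1})·fs/2` and
`a_t = (x_{t+1} − 2x_t + x_{t−1})·fs²`, with endpoints copied from the
nearest interior frame so every derived series has the length of the
recording.  Optional Gaussian smoothing of the positions (sigma in
frames, default 0 = off) is applied before differencing; tracking
pipelines differ in how much smoothing their detectors already
perform, so this is left to the user.  Central differencing is exact
for quadratic motion, which anchors the unit tests.

## Collision resolution

During contacts a tracker produces one merged detection.
`split_merged_blob` fits a two-component Gaussian mixture (EM,
spherical covariance, k-means++ initialization from a seeded stream)
to the merged pixel samples and returns the component means as
candidate centroids.  `resolve_identities` then propagates identity
through the collision greedily: at each frame, with the previous two
identified frames held fixed, the total absolute linear acceleration
`Σ_fish |x_t − 2x_{t−1} + x_{t−2}|` is evaluated for both possible
candidate-to-fish assignments and the smaller is kept (ties keep the
previous frame's ordering).  The identities on both sides of the
collision are known from the tracker; the two frames before the
collision seed the recursion and the frame after it closes the check.

A greedy pass and an endpoint constraint can conflict.  When the final
greedy state would prefer the swap of the post-anchor, the interval is
returned with its best-effort assignment and an `anchor-mismatch`
status rather than silently backtracking — whether backtracking is
ever the right repair depends on the upstream tracker's reliability,
which this package cannot judge.  An exhaustive mode
(`resolve_identities_exhaustive`) enumerates all 2^L assignments for
intervals up to 12 frames and serves as the optimality oracle in the
tests; for constant-velocity crossings the greedy result equals the
global optimum because the true assignment has zero acceleration.

## Egocentric features and the attack classifier

A classification window covers frames `[t−K, t]` with K = 10 (0.5 s at
20 Hz) by default.  The window is expressed in a rigid frame anchored
at `t−K`: the origin is the joint centre of mass of the two fish and
the +x axis is the unit vector from the focal fish to its partner.
Four series — focal positions, partner positions, focal velocities,
partner velocities — are mapped into this frame (velocities rotate but
do not translate, being direction quantities) and concatenated into a
vector of length 8(K+1).  The construction removes global translation
and rotation exactly (tested to 1e-9) while preserving chirality, so
left- and right-turning manoeuvres remain distinguishable.  Windows
whose anchor frame has coincident fish are degenerate and score 0 with
a warning.

The scorer is a multilayer perceptron with two rectifier hidden layers
of 250 units and a cross-entropy loss, trained with Adam
(learning rate 1e-3, up to 120 epochs, deterministic given the seed).
Features are standardized before training.  One shared network scores
both fish: the recording is evaluated twice per frame, once with each
fish as focal.  Thresholding the scores at 0.5 gives attack labels;
the per-frame role is the labelled fish, or with both labelled the
fish with the higher score (ties to fish 1).  Raising the threshold
can only remove attack frames (monotonicity is property-tested).
Trained models are saved as a plain `.npz` weight archive with JSON
metadata, and scoring runs an internal forward pass, so saved models
do not depend on the training backend.

## Kinematic and assessment statistics

*Attack fractions* are computed per fish in non-overlapping windows
(default 2 min); the *total* attack fraction is the sum of the two
individual fractions and may exceed 1 when both fish attack at once.
*Burst fractions* count frames with acceleration magnitude strictly
above 128 cm s⁻².  The *dominance rule* declares a fish dominant at
time t if it delivered strictly more than 90 % of the attack-role
frames in the preceding 4 minutes.

*Phase segmentation* is this package's operationalization of the
qualitative phase structure: each 2-minute window is quiet
(total attack fraction < 0.02, configurable) or active; an active
window is asymmetric when the dominance rule singles out a fish at the
window's end (falling back to the whole available history before the
first full 4-minute window) and symmetric otherwise; quiet windows are
pre-fight before any activity and unresolved afterwards; adjacent
same-label windows merge.  The 0.02 floor is a design choice — it
corresponds to a little over two seconds of attack per two-minute
window, below which phase labels would be driven by classifier noise.

*Attack-aligned waveforms* average attacker and defender speed (and
acceleration magnitude) across attack events, aligned at onset and
truncated at the median event duration; events are maximal
constant-attacker runs of at least 3 frames (shorter runs are treated
as label noise), and at each time point the mean is over events still
in progress.

The *exact binomial test* sums the binomial pmf directly (integer
arithmetic at p₀ = 0.5); the two-tailed value doubles the smaller tail
and caps at 1, which at p₀ = 0.5 coincides with the
small-probability-sum convention by symmetry.  Fight-duration
regression is ordinary least squares with intercept on the sizes of
the larger and smaller contestant, with per-coefficient t-test
p-values (statsmodels).

## Forcemaps

For every frame in which a fish holds the requested role, the
partner's position is expressed in the focal frame — focal at the
origin, looking along +y (heading taken from velocity, since body
orientation is unavailable from centroids), right along +x — and the
focal acceleration is decomposed into speeding (parallel to velocity)
and turning (perpendicular, positive rightward) components, an exact
orthogonal split (`speeding² + turning² = |a|²`).  Partner positions
are binned on a 21×21 grid spanning ±3 body lengths per axis and the
mean of each component is taken per bin; bins with fewer than 20
samples (configurable) are masked, and the occupancy density is
normalized over unmasked bins.

Wall effects are excluded per phase: contest-phase maps use only
frames with both fish at least `wall_margin` (5 cm) from every wall;
post-resolution maps, where the chase hugs the walls, drop frames with
either fish within `corner_margin` (5 cm) of a corner.  Zero-speed
frames have no defined heading and are skipped with a count.
Mirroring the arena negates turning maps and preserves speeding maps,
a property the test suite checks on simulated data.

## Splash quantification

A splash is modelled as: contact (centroid distance below half a body
length), an acceleration spike (default 1280 cm s⁻², ten times the
burst threshold), a heading reversal, and a rapid separation to at
least two body lengths within a second.  The orientation-change index
of an event is the cosine between the heading 2 frames before and
2 frames after the event (±100 ms at 20 Hz); −1 is a full reversal,
+1 unchanged, and the index is invariant to global rotation.  The
event index is the mean over the two fish and must fall below −0.5 for
detection; detections within 1 s of an accepted event are suppressed.
The cosine definition and the 2-frame lags are design choices — they
reproduce both defining endpoints and tolerate the one-frame timing
ambiguity of a sub-50-ms reversal sampled at 20 Hz.  In real data
splashes are rare and short enough that manual annotation remains the
reference; the detector is offered as a screening tool and is
validated here against injected synthetic events (precision and recall
≥ 0.9 on the bundled simulations).

## The chase game

Post-resolution chases are modelled as a zero-sum game.  Both fish
swim at speed v, which requires force F(v) at metabolic cost C(F); the
winner could bite by producing extra force δF (cost C(F + δF)),
inflicting cost C_b on the loser.  Rewards are cost differences:
r_w = C_l − C_w = −r_l.  With C strictly convex the biting premium
ΔC(F) = C(F + δF) − C(F) increases in F, so there is a unique chase
intensity at which biting stops paying: ΔC(F*) = C_b.  If a
physiological force cap F_max binds first, the equilibrium is pinned
at F(v_eq) = F_max − δF.  If even biting at rest exceeds C_b
(C_b < C(δF)) the interior root would be negative and the model
returns F* = 0 with a boundary flag — sustained chasing cannot be
supported.  Equilibrium speed is v_eq = (F*/k)^{1/γ}, non-decreasing
in C_b and constant once capped: more damaging bites predict faster
chases.

The laws are parameterized as power laws, F(v) = k·v^γ (γ ≥ 1) and
C(F) = c·F^β (β > 1) — the minimal family satisfying monotone force
and strictly convex cost; both exponents are configurable so other
laws can be slotted in.  Root-finding uses bracketing (brentq,
xtol 1e-12) on the monotone premium; for the quadratic cost law the
closed form F* = (C_b − δF²)/(2δF) provides an exact cross-check, and
an independently coded Newton iteration agrees with the bracketing
root to 1e-8 on well-conditioned models (for nearly linear cost laws,
β close to 1, the root grows so large that evaluating ΔC is
cancellation-dominated and no root-finder is meaningful there).

## The fight simulator

`simulate_fight` is a discrete-time agent model, not a hydrodynamic
one: each fish is a point mass with a heading and a scalar speed
updated once per frame, reflective walls, and Gaussian speed noise.
It emulates the statistical structure the analyses assume:

- **Phases.**  Default schedule 30 % pre-fight / 20 % symmetric /
  50 % asymmetric of a 600 s fight (configurable).  Cruising speed
  5.3 cm/s; attack-drive speeds 10.5 cm/s (contest) and 13.7 cm/s
  (post-resolution), matching the scale of real contests.
- **Attack bouts** arrive as a Poisson process (6/min by default,
  mean duration 2 s) with alternating attacker identity in the
  contest phase and a fixed winner afterwards.
- **Attacker rule.**  The attacker steers toward the defender and
  regulates tangential acceleration with the distance-error kernel
  `a = gain·(d − d₀)` clipped to ±80 cm s⁻² — attraction beyond the
  preferred distance d₀, repulsion within it.  d₀ is 0.5 body lengths
  in the contest phase and 1 body length in chases.
- **Defender rule.**  The defender accelerates away with the mirrored
  kernel.  In the contest phase, at close range, it steers to hold
  the attacker at its flank (a net turn *toward* the attacker's
  side), which maintains the perpendicular "T" configuration; in the
  post-resolution phase the turn-toward gain is zero and the chase is
  a straight flight with the attacker roughly a body length behind.
- **Splashes** are injected on a schedule: the pair is driven into a
  head-on contact in the arena interior (so the escape is not
  immediately wall-reflected), both headings reverse with the pair
  momentarily stalled at the contact frame, a 70 cm/s impulse fires
  on the next frame, and separation beyond two body lengths is
  enforced within a second.
- **Collisions** for resolver benchmarks come from a separate fixture
  generator: two curvature-bounded tracks on crossing courses, with
  the middle frames emitted as per-frame shuffled candidate pairs
  flanked by identified anchors.

All randomness flows from one seeded `numpy` Generator, so identical
configs give bitwise-identical recordings.  The interaction gains are
free parameters chosen once to produce clearly structured speeding and
turning maps at the default arena scale; they are not fitted to any
dataset.

What the simulator does **not** emulate — body shape and posture, fin
kinematics, hydrodynamic coupling, 3-D depth changes, appearance and
colour change, tracker pixel noise — bounds what passing tests show:
they demonstrate that the analysis pipeline recovers the rules the
generator implements at realistic kinematic scales, not that a
classifier trained on synthetic fights transfers to video-tracked
animals.

## Problem sizes and numerical choices

The test suite and acceptance script run on deliberately modest
problem sizes chosen as the smallest that make the statistics stable:
600 s fights for classifier training/evaluation (three training
fights, 4 000 balanced windows), 1 200 s single-phase runs for
forcemap kernel recovery, 1 800 s for the windowed speed/attack
correlation, 200 collision fixtures of 3–20 frames, and four 400 s
runs with four injected splashes each for detector validation.
Ties in the greedy resolver keep the previous ordering; degenerate
geometry (coincident fish, zero speed) raises a dedicated error in
single-frame APIs and is skipped with a count in bulk APIs; score
thresholding is strict (`>`), as is the burst threshold and the
dominance fraction.

## Known limitations

- Heading is derived from velocity; at near-zero speeds the focal
  frame and the orientation-change index are undefined, and such
  frames are dropped rather than interpolated.
- The greedy resolver does not backtrack on anchor mismatch; flagged
  intervals should be re-examined upstream.
- The phase segmentation is window-quantized (2 min), so phase
  boundaries inherit that resolution.
- The splash detector's thresholds are phenomenological; on real
  recordings they should be validated against manual annotation
  before use.
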