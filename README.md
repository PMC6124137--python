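# fightkit

Trajectory-level analysis of dyadic fish contests.

Staged fights between two zebrafish unfold as a sequence of phases: a
quiet pre-fight period, a *symmetric* (contest) phase in which both
individuals trade attacks, and an *asymmetric* (post-resolution) phase
in which the winner chases the loser. `fightkit` takes the per-frame
2-D centroid trajectories of such a pair (20 Hz by default) and turns
them into quantitative descriptions of the fight, for behavioural
ecologists and neuroethologists who work with tracked contest data:

- **Collision identity resolution** — when two fish touch, a tracker
  sees one merged blob.  A two-component Gaussian mixture splits the
  blob into candidate centroids, and identities are propagated through
  the collision by *greedy acceleration minimization*: at each frame,
  holding the previous two identified frames fixed, choose the
  candidate assignment with the smaller summed second-difference
  magnitude `Σ_fish |x_t − 2x_{t−1} + x_{t−2}|`, subject to the
  identities anchored on both sides of the collision.
- **Automated ethograms** — short egocentric trajectory windows
  (translation- and rotation-invariant, chirality-preserving) are
  scored by a multilayer perceptron (two ReLU hidden layers of 250
  units, cross-entropy loss) into a per-frame, per-fish attack
  probability; thresholding yields attack labels and dynamic
  attacker/defender roles.
- **Kinematic and assessment statistics** — windowed attack fractions,
  high-acceleration burst fractions (|a| > 128 cm s⁻²), exact binomial
  tests, Pearson correlations, the dominance rule (> 90 % of attacks
  over the preceding 4 min), phase segmentation, attack-aligned
  velocity waveforms, and OLS regression of fight duration on
  contestant sizes.
- **Forcemaps** — maps of the focal fish's mean *speeding* force
  (acceleration component parallel to its velocity) and *turning*
  force (perpendicular, positive to the right) as a function of the
  partner's position in the focal frame, with wall/corner exclusion
  rules per phase.
- **Splash metrics** — the orientation-change index (cosine of the
  heading change across an event: −1 for a 180° reversal, +1 for
  unchanged), an automatic splash detector, and event-aligned traces.
- **Chase game theory** — a zero-sum model of post-resolution chases
  with force law F(v) = k·v^γ and convex cost law C(F) = c·F^β.  The
  equilibrium chase force solves ΔC(F) = C(F+δF) − C(F) = C_b (the
  biting premium equals the damage a bite inflicts), or sits at
  F_max − δF when force is capped; equilibrium chase speed rises with
  bite damage.
- **Synthetic fights** — a seeded agent-based simulator producing
  recordings with ground-truth attack labels, phases, collisions and
  splash events, used throughout the test suite and the acceptance
  script.

## Worked example

```python
import numpy as np
from fightkit import SimulationConfig, simulate_fight, Ethogram
from fightkit.kinematics import attack_fraction_series, pearson_r
from fightkit.chase_game import ChaseGameModel, comparative_statics

# a 30-minute fight: pre-fight, contest, then post-resolution chasing
rec, truth = simulate_fight(SimulationConfig(duration_s=1800.0, seed=1))
eth = Ethogram.from_labels(truth.labels, truth.role)

af = attack_fraction_series(eth, window_s=120.0)
speed = [rec.speeds[int(r.window_start_s * 20):
                    int(r.window_start_s * 20) + int(r.n_frames)].mean()
         for r in af.itertuples()]
print(f"speed vs attack fraction: r = {pearson_r(speed, af['total']):.2f}")

model = ChaseGameModel(k=1.0, gamma=1.0, c=1.0, beta=2.0, delta_F=1.0)
print(comparative_statics(model, [1.0, 5.0, 10.0]).to_string(index=False))
```

Output:

```
speed vs attack fraction: r = 0.96
 C_b  F_star  v_eq   regime
 1.0     0.0   0.0 interior
 5.0     2.0   2.0 interior
10.0     4.5   4.5 interior
```

The correlation shows that windows with more attacking are windows
with faster swimming — the energetic signature of attacks driving both
fish.  The game-theory table shows the equilibrium chase force and
speed rising as bites become more damaging (C_b): a winner chases
exactly hard enough that biting stops being worth its extra cost.

A command-line interface mirrors the library
(`fightkit simulate|resolve|train|score|ethogram|kinematics|forcemap|splash|game`),
reading YAML run configs and writing CSV/HDF5/JSON.

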