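"""Seeded two-fish fight simulator with ground-truth annotations.

The simulator is an agent-based, discrete-time model of a staged
dyadic contest.  Each fish is a point mass with first-order velocity
control (a heading angle and a scalar speed updated once per frame).
A fight is divided into three phases:

* **pre-fight** — both fish perform a correlated random walk at a low
  cruising speed;
* **symmetric** (contest) phase — attack bouts occur with alternating
  attacker identity.  The attacker regulates its tangential
  acceleration with a distance-error kernel ``a = gain * (d - d0)``
  (attraction beyond the preferred distance d0, repulsion within it)
  while steering toward the defender; the defender flees and
  additionally turns *toward* the side the attacker is on, which
  maintains the flank-on "T" configuration;
* **asymmetric** (post-resolution) phase — one fish attacks in every
  bout, the preferred distance is larger and the defender's
  turn-toward gain is zero, producing straight high-speed chases.

Walls are handled by reflection.  Splash manoeuvres can be injected on
a schedule: the pair is driven into contact, then both headings are
reversed with a large acceleration impulse and the fish separate by at
least two body lengths within a second.  All randomness flows from a
single ``numpy`` Generator seeded from the config, so identical
configs give bitwise-identical recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ArenaConfig, FightRecording, ROLE_NONE
from .errors import ConfigError, SamplingError

PRE_FIGHT, SYMMETRIC, ASYMMETRIC = "pre-fight", "symmetric", "asymmetric"


@dataclass
class SimulationConfig:
    """Conditions of a simulated fight.

    Phase speeds default to the scale of real contests: cruising at
    about 5.3 cm/s before the fight, attack-drive speeds of about
    10.5 cm/s in the contest phase and 13.7 cm/s in the post-resolution
    phase.  Preferred attacker-defender distances are about half a body
    length during contest-phase attacks and a full body length during
    post-resolution chases.  Interaction gains are free parameters of
    the generator, set to produce clearly structured speeding/turning
    maps at the default arena scale.
    """

    duration_s: float = 600.0
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    #: ((start_s, end_s, label), ...); None = 30% pre / 20% sym / 50% asym
    phases: tuple | None = None
    speed_prefight: float = 5.3
    speed_symmetric: float = 10.5
    speed_asymmetric: float = 13.7
    attack_rate_per_min: float = 6.0
    attack_mean_duration_s: float = 2.0
    attack_min_duration_s: float = 0.5
    attraction_gain: float = 30.0       # cm s^-2 per cm of distance error
    d0_symmetric_bl: float = 0.5        # preferred distance, body lengths
    d0_asymmetric_bl: float = 1.0
    kernel_accel_max: float = 80.0      # clip for the speeding kernels
    attacker_turn_gain: float = 6.0     # rad/s toward the defender
    defender_flee_gain: float = 5.0     # rad/s away from the attacker
    defender_turn_gain: float = 3.5     # rad/s toward attacker's side (sym)
    speed_relax: float = 2.0            # 1/s relaxation to target speed
    heading_noise: float = 1.0          # rad/sqrt(s), baseline random walk
    speed_noise: float = 1.0            # cm/s/sqrt(s) velocity noise
    contact_dist_bl: float = 0.5        # contact threshold, body lengths
    collision_prob: float = 1.0         # P(a contact run is a collision)
    splash_rate_per_min: float = 0.0    # Poisson rate within symmetric phase
    splash_times_s: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ("duration_s", "attack_mean_duration_s",
                    "attack_min_duration_s")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        nonneg = ("speed_prefight", "speed_symmetric", "speed_asymmetric",
                  "attack_rate_per_min", "attraction_gain",
                  "d0_symmetric_bl", "d0_asymmetric_bl", "kernel_accel_max",
                  "attacker_turn_gain", "defender_flee_gain",
                  "defender_turn_gain", "speed_relax", "heading_noise",
                  "speed_noise", "contact_dist_bl", "splash_rate_per_min")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.collision_prob <= 1:
            raise ConfigError("collision_prob must be in [0, 1]")
        for t in self.splash_times_s:
            if not 0 <= t < self.duration_s:
                raise ConfigError("splash times must fall within duration")
        prev_end = 0.0
        for start, end, label in self.phase_schedule():
            if label not in (PRE_FIGHT, SYMMETRIC, ASYMMETRIC):
                raise ConfigError(f"unknown phase label {label!r}")
            if start < prev_end or end <= start or end > self.duration_s:
                raise ConfigError("phase intervals must be disjoint, "
                                  "ordered and within duration")
            prev_end = end

    def phase_schedule(self) -> tuple:
        if self.phases is not None:
            return tuple(self.phases)
        d = self.duration_s
        return ((0.0, 0.3 * d, PRE_FIGHT),
                (0.3 * d, 0.5 * d, SYMMETRIC),
                (0.5 * d, d, ASYMMETRIC))


@dataclass
class GroundTruth:
    """Per-frame annotations produced alongside a simulated recording."""

    labels: np.ndarray          # (T, 2) bool, attack label per fish
    role: np.ndarray            # (T,) int8, attacker index or ROLE_NONE
    phase: np.ndarray           # (T,) unicode phase label
    splash_frames: np.ndarray   # frames of injected splash reversals
    collision_intervals: list   # [(start, end)] inclusive contact runs
    config: SimulationConfig


def _wrap(angle):
    return (angle + math.pi) % (2.0 * math.pi) - math.pi


def _turn_toward(heading, target, max_step):
    return heading + np.clip(_wrap(target - heading), -max_step, max_step)


def _phase_per_frame(cfg: SimulationConfig, n: int, fs: float) -> np.ndarray:
    phase = np.full(n, PRE_FIGHT, dtype="<U10")
    for start, end, label in cfg.phase_schedule():
        i0, i1 = int(round(start * fs)), min(int(round(end * fs)), n)
        phase[i0:i1] = label
    return phase


def _schedule_bouts(cfg: SimulationConfig, rng, n: int, fs: float):
    """Poisson bout schedule -> (labels (T,2) bool, role (T,))."""
    labels = np.zeros((n, 2), dtype=bool)
    role = np.full(n, ROLE_NONE, dtype=np.int8)
    if cfg.attack_rate_per_min == 0:
        return labels, role
    mean_gap = 60.0 / cfg.attack_rate_per_min
    for start, end, label in cfg.phase_schedule():
        if label == PRE_FIGHT:
            continue
        t = start + rng.exponential(mean_gap)
        while t < end:
            dur = cfg.attack_min_duration_s + rng.exponential(
                max(cfg.attack_mean_duration_s - cfg.attack_min_duration_s,
                    1e-6))
            attacker = int(rng.integers(2)) if label == SYMMETRIC else 0
            i0 = int(round(t * fs))
            i1 = min(int(round(min(t + dur, end) * fs)), n)
            labels[i0:i1, attacker] = True
            role[i0:i1] = attacker
            t = max(t + dur, t) + rng.exponential(mean_gap)
    return labels, role


def _splash_schedule(cfg: SimulationConfig, rng, fs: float) -> list:
    times = list(cfg.splash_times_s)
    if cfg.splash_rate_per_min > 0:
        for start, end, label in cfg.phase_schedule():
            if label != SYMMETRIC:
                continue
            t = start + rng.exponential(60.0 / cfg.splash_rate_per_min)
            while t < end:
                times.append(t)
                t += rng.exponential(60.0 / cfg.splash_rate_per_min)
    return sorted(times)


def simulate_fight(config: SimulationConfig):
    """Run the agent simulation.

    Returns
    -------
    (FightRecording, GroundTruth)
    """
    cfg = config
    arena = cfg.arena
    fs = arena.frame_rate
    dt = 1.0 / fs
    n = int(round(cfg.duration_s * fs))
    rng = np.random.default_rng(cfg.seed)
    bl = arena.body_length

    phase = _phase_per_frame(cfg, n, fs)
    labels, role = _schedule_bouts(cfg, rng, n, fs)
    splash_times = _splash_schedule(cfg, rng, fs)
    splash_iter = iter(splash_times)
    next_splash = next(splash_iter, None)
    splash_frames: list[int] = []
    # splash machinery: mode is None | "approach" | "escape"
    splash_mode = None
    splash_until = -1
    splash_impulse = -1
    splash_start = -1

    phase_speed = {PRE_FIGHT: cfg.speed_prefight,
                   SYMMETRIC: cfg.speed_symmetric,
                   ASYMMETRIC: cfg.speed_asymmetric}
    d0_of = {SYMMETRIC: cfg.d0_symmetric_bl * bl,
             ASYMMETRIC: cfg.d0_asymmetric_bl * bl}

    pos = np.empty((2, 2))
    pos[0] = (0.35 * arena.width, 0.5 * arena.height)
    pos[1] = (0.65 * arena.width, 0.5 * arena.height)
    pos += rng.normal(0.0, 1.0, size=(2, 2))
    heading = rng.uniform(-math.pi, math.pi, size=2)
    speed = np.full(2, cfg.speed_prefight)

    out = np.empty((n, 2, 2))
    sq = math.sqrt(dt)
    margin = 0.3  # cm kept clear of the walls after reflection

    for t in range(n):
        ph = phase[t]
        attacking = role[t] != ROLE_NONE

        # --- splash state machine -------------------------------------
        interior = min(pos[:, 0].min(), arena.width - pos[:, 0].max(),
                       pos[:, 1].min(), arena.height - pos[:, 1].max())
        if splash_mode is None and next_splash is not None \
                and t * dt >= next_splash and ph != PRE_FIGHT \
                and interior > 2.5 * bl:
            # stage the contact only in the arena interior so the
            # escape impulse is not immediately reflected by a wall
            splash_mode = "approach"
            splash_start = t
            splash_until = t + int(round(3.0 * fs))  # give up after 3 s
        if splash_mode == "approach":
            delta = pos[1] - pos[0]
            d = float(np.linalg.norm(delta))
            if d < cfg.contact_dist_bl * bl * 0.8 and t - splash_start >= 4:
                # contact reached: both headings reverse and the pair
                # momentarily stalls, so the event frame itself is
                # still in contact; the separating impulse fires on
                # the next frame
                heading += math.pi
                speed[:] = 0.5
                splash_frames.append(t)
                splash_mode = "escape"
                splash_impulse = t + 1
                splash_until = t + int(round(1.0 * fs))
                next_splash = next(splash_iter, None)
            elif t >= splash_until:
                splash_mode = None          # could not stage the contact
                next_splash = next(splash_iter, None)
            else:
                # stage a head-on contact: both fish face each other
                # and close a fixed fraction of the remaining distance
                # per frame (no overshoot), so the later escape is a
                # genuine heading reversal for both
                bearing01 = math.atan2(delta[1], delta[0])
                heading[0] = bearing01
                heading[1] = _wrap(bearing01 + math.pi)
                speed[0] = min(25.0, 0.25 * d / dt)
                speed[1] = min(4.0, 0.25 * d / dt)
        elif splash_mode == "escape":
            delta = pos[1] - pos[0]
            nrm = float(np.linalg.norm(delta))
            if nrm > 1e-9:
                away = math.atan2(delta[1], delta[0])
                heading[0] = _turn_toward(heading[0], away + math.pi,
                                          12.0 * dt)
                heading[1] = _turn_toward(heading[1], away, 12.0 * dt)
            if t == splash_impulse:
                speed[:] = 70.0             # the acceleration impulse
            else:
                speed += (max(2.5 * bl / 1.0, 12.0) - speed) * min(
                    3.0 * dt, 1.0)
            if t >= splash_until and nrm >= 2.0 * bl:
                splash_mode = None

        # --- attack-bout dynamics -------------------------------------
        if splash_mode is None and attacking:
            att = int(role[t])
            dfn = 1 - att
            delta = pos[dfn] - pos[att]
            d = float(np.linalg.norm(delta))
            if d < 1e-9:
                bearing = heading[att]
            else:
                bearing = math.atan2(delta[1], delta[0])
            d0 = d0_of.get(ph, cfg.d0_symmetric_bl * bl)
            v_phase = phase_speed.get(ph, cfg.speed_symmetric)

            # attacker: steer at the defender, distance-error speeding
            heading[att] = _turn_toward(heading[att], bearing,
                                        cfg.attacker_turn_gain * dt)
            a_k = float(np.clip(cfg.attraction_gain * (d - d0),
                                -cfg.kernel_accel_max, cfg.kernel_accel_max))
            speed[att] = float(np.clip(speed[att] + a_k * dt,
                                       1.0, 1.6 * v_phase))

            # defender heading.  Asymmetric phase (and distant
            # attackers): flee straight along the line of sight.
            # Symmetric phase at close range: hold the attacker at the
            # flank instead — steer toward a heading perpendicular to
            # the attacker's bearing, on the attacker's current side.
            # This is a net turn toward the attacker and maintains the
            # T-configuration.
            bearing_to_att = _wrap(bearing + math.pi)
            t_hold = (ph == SYMMETRIC and cfg.defender_turn_gain > 0
                      and d < 2.5 * d0)
            if t_hold:
                # side of the attacker in the defender's frame:
                # positive = attacker on the defender's right
                rhat = (math.sin(heading[dfn]), -math.cos(heading[dfn]))
                x_rel = -delta[0] * rhat[0] - delta[1] * rhat[1]
                side = math.copysign(1.0, x_rel) if abs(x_rel) > 1e-9 \
                    else 1.0
                target = _wrap(bearing_to_att + side * math.pi / 2.0)
                heading[dfn] = _turn_toward(heading[dfn], target,
                                            cfg.defender_turn_gain * dt)
            else:
                heading[dfn] = _turn_toward(heading[dfn], bearing,
                                            cfg.defender_flee_gain * dt)
            # mirrored speeding kernel: accelerate when the attacker
            # closes in, ease off when it falls behind
            a_f = float(np.clip(cfg.attraction_gain * (2.0 * d0 - d),
                                -cfg.kernel_accel_max, cfg.kernel_accel_max))
            speed[dfn] = float(np.clip(
                speed[dfn] + a_f * dt
                + cfg.speed_relax * (v_phase - speed[dfn]) * dt,
                1.0, 1.6 * v_phase))
        elif splash_mode is None:
            # correlated random walk at cruising speed
            heading += rng.normal(0.0, cfg.heading_noise * sq, size=2)
            speed += cfg.speed_relax * (cfg.speed_prefight - speed) * dt

        speed = np.clip(speed + rng.normal(0.0, cfg.speed_noise * sq,
                                           size=2), 0.2, 80.0)
        heading = _wrap(heading)

        # --- integrate and reflect ------------------------------------
        pos = pos + speed[:, None] * np.stack(
            [np.cos(heading), np.sin(heading)], axis=1) * dt
        for f in (0, 1):
            x, y = pos[f]
            if x < margin:
                pos[f, 0] = 2.0 * margin - x
                heading[f] = _wrap(math.pi - heading[f])
            elif x > arena.width - margin:
                pos[f, 0] = 2.0 * (arena.width - margin) - x
                heading[f] = _wrap(math.pi - heading[f])
            if y < margin:
                pos[f, 1] = 2.0 * margin - y
                heading[f] = _wrap(-heading[f])
            elif y > arena.height - margin:
                pos[f, 1] = 2.0 * (arena.height - margin) - y
                heading[f] = _wrap(-heading[f])
        pos[:, 0] = np.clip(pos[:, 0], 0.0, arena.width)
        pos[:, 1] = np.clip(pos[:, 1], 0.0, arena.height)
        out[t] = pos

    rec = FightRecording(out, arena)

    # contact runs -> collision intervals (a run counts as a collision
    # with probability collision_prob)
    contact = rec.distances() < cfg.contact_dist_bl * bl
    collision_intervals = []
    for start, end in _runs(contact):
        if rng.random() < cfg.collision_prob:
            collision_intervals.append((start, end))

    gt = GroundTruth(labels=labels, role=role, phase=phase,
                     splash_frames=np.array(splash_frames, dtype=int),
                     collision_intervals=collision_intervals, config=cfg)
    return rec, gt


def _runs(mask: np.ndarray):
    """Maximal True runs of a boolean series as (start, end) inclusive."""
    m = np.asarray(mask, bool)
    if m.size == 0:
        return []
    diff = np.diff(m.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0])
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size - 1)
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# collision fixtures


@dataclass
class CollisionFixture:
    """A synthetic collision with shuffled candidates and known truth.

    ``pre_anchor`` holds the two identified frames immediately before
    the collision (shape (2, 2, 2): frame, fish, xy); ``post_anchor``
    the identified frame immediately after (shape (2, 2)); and
    ``candidates`` the per-frame unordered coordinate pairs (shape
    (L, 2, 2)).  ``true_perm[t] == 1`` means ``candidates[t]`` lists
    fish 1 first.
    """

    pre_anchor: np.ndarray
    candidates: np.ndarray
    post_anchor: np.ndarray
    true_perm: np.ndarray
    true_positions: np.ndarray


def make_collision_fixture(config: SimulationConfig, seed: int,
                           n_frames: int = 10,
                           constant_velocity: bool = False
                           ) -> CollisionFixture:
    """Generate one crossing-track collision fixture.

    Two smooth, curvature-bounded tracks are laid on crossing courses
    through the arena centre; the middle ``n_frames`` frames become the
    unlabeled candidate pairs (shuffled per frame), flanked by two
    identified pre-anchor frames and one post-anchor frame.  With
    ``constant_velocity=True`` the tracks are straight lines at
    constant speed.
    """
    if n_frames < 0:
        raise ConfigError("n_frames must be >= 0")
    rng = np.random.default_rng(seed)
    arena = config.arena
    dt = 1.0 / arena.frame_rate
    total = n_frames + 3
    center = np.array([arena.width / 2.0, arena.height / 2.0])

    base = rng.uniform(-math.pi, math.pi)
    headings0 = np.array([base, base + math.pi + rng.uniform(-0.9, 0.9)])
    speeds0 = rng.uniform(6.0, 14.0, size=2)

    tracks = np.empty((total, 2, 2))
    for f in (0, 1):
        h = headings0[f]
        s = speeds0[f]
        # start so that the track passes near the centre mid-collision,
        # with a small lateral offset so the paths actually cross
        offset = rng.uniform(-1.0, 1.0, size=2)
        p = center + offset - np.array([math.cos(h), math.sin(h)]) \
            * s * dt * (total / 2.0)
        omega = 0.0
        for t in range(total):
            tracks[t, f] = p
            if not constant_velocity:
                omega = float(np.clip(omega + rng.normal(0.0, 1.5) * dt,
                                      -2.0, 2.0))
                h += omega * dt
                s = float(np.clip(s + rng.normal(0.0, 4.0) * dt, 3.0, 18.0))
            p = p + np.array([math.cos(h), math.sin(h)]) * s * dt

    pre_anchor = tracks[:2]
    post_anchor = tracks[-1]
    true_positions = tracks[2:-1]
    true_perm = rng.integers(0, 2, size=n_frames).astype(np.int8)
    candidates = true_positions.copy()
    swap = true_perm == 1
    candidates[swap] = candidates[swap][:, ::-1]
    return CollisionFixture(pre_anchor, candidates, post_anchor,
                            true_perm, true_positions)


# ---------------------------------------------------------------------------
# classifier datasets


def make_classifier_dataset(config: SimulationConfig, n_windows: int = 2000,
                            balance: float = 0.5, K: int = 10,
                            seed: int = 0, n_fights: int = 2):
    """Balanced labelled feature windows from simulated fights.

    Simulates ``n_fights`` fights (seeds derived from ``seed``),
    extracts the egocentric feature vector of every (frame, fish)
    sample with a complete window, and samples ``n_windows`` of them
    without replacement at the requested attack/non-attack balance.

    Returns
    -------
    X : (n_windows, 8*(K+1)) array
    y : (n_windows,) int array (1 = attack)
    """
    from .classifier import FeatureConfig, egocentric_feature_matrix

    if not 0.0 <= balance <= 1.0:
        raise ConfigError("balance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fcfg = FeatureConfig(K=K)
    X_parts, y_parts = [], []
    for i in range(n_fights):
        sub = replace(config, seed=int(rng.integers(2 ** 31)))
        rec, gt = simulate_fight(sub)
        frames = np.arange(K, rec.n_frames)
        for focal in (0, 1):
            X, valid = egocentric_feature_matrix(rec, focal, fcfg, frames)
            X_parts.append(X[valid])
            y_parts.append(gt.labels[frames, focal][valid].astype(int))
    X_all = np.concatenate(X_parts)
    y_all = np.concatenate(y_parts)

    n_pos = int(round(n_windows * balance))
    n_neg = n_windows - n_pos
    pos_idx = np.nonzero(y_all == 1)[0]
    neg_idx = np.nonzero(y_all == 0)[0]
    if len(pos_idx) < n_pos or len(neg_idx) < n_neg:
        raise SamplingError(
            f"requested {n_pos} attack / {n_neg} non-attack windows but "
            f"only {len(pos_idx)} / {len(neg_idx)} are available")
    take = np.concatenate([rng.choice(pos_idx, n_pos, replace=False),
                           rng.choice(neg_idx, n_neg, replace=False)])
    rng.shuffle(take)
    return X_all[take], y_all[take]
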