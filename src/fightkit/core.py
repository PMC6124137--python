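"""Core domain types for dyadic fight recordings.

Coordinate convention used throughout the package: origin at the
bottom-left corner of the arena, x to the right, y up, lengths in cm.
Frames are 0-based integers and time = frame / frame_rate.  Every
recording holds exactly two individuals, indexed 0 and 1 (called
"fish1" and "fish2" in file formats and user-facing output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import BoundsError, ConfigError, InsufficientDataError

#: role code meaning "nobody is attacking" (otherwise the role is the
#: 0-based index of the attacking fish).
ROLE_NONE = -1

ROLE_NAMES = {ROLE_NONE: "none", 0: "fish1", 1: "fish2"}
ROLE_CODES = {v: k for k, v in ROLE_NAMES.items()}


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry of the fight arena and the recording rate.

    Parameters
    ----------
    width, height : float
        Arena extent in cm (x and y respectively).
    frame_rate : float
        Sampling rate of the trajectories in Hz.
    wall_margin : float
        Minimum distance (cm) from the nearest wall for a frame to be
        retained in symmetric-phase forcemaps.
    corner_margin : float
        Minimum distance (cm) from the nearest corner for a frame to be
        retained in asymmetric-phase forcemaps.
    body_length : float
        Nominal fish body length in cm; used to express interaction
        distances in body lengths.
    """

    width: float = 32.0
    height: float = 24.0
    frame_rate: float = 20.0
    wall_margin: float = 5.0
    corner_margin: float = 5.0
    body_length: float = 3.0

    def __post_init__(self) -> None:
        for name in ("width", "height", "frame_rate", "wall_margin",
                     "corner_margin", "body_length"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        half = min(self.width, self.height) / 2.0
        if self.wall_margin >= half or self.corner_margin >= half:
            raise ConfigError("margins must be < min(width, height)/2")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


def derive_motion(positions, frame_rate, smooth_sigma: float = 0.0):
    """Velocity, acceleration and speed of one position series.

    Central differences: v_t = (x_{t+1} - x_{t-1}) * fs / 2 and
    a_t = (x_{t+1} - 2 x_t + x_{t-1}) * fs**2; the endpoint values are
    copied from the nearest interior frame.  With ``smooth_sigma > 0``
    the positions are Gaussian-smoothed (sigma in frames) before
    differencing.

    Parameters
    ----------
    positions : (T, 2) array
        Per-frame (x, y) positions of one fish, cm.
    frame_rate : float
        Sampling rate in Hz.

    Returns
    -------
    velocity : (T, 2) array, cm/s
    acceleration : (T, 2) array, cm/s^2
    speed : (T,) array, cm/s
    """
    x = np.asarray(positions, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("positions must have shape (T, 2)")
    if x.shape[0] < 3:
        raise InsufficientDataError("derive_motion needs at least 3 frames")
    if smooth_sigma > 0:
        x = gaussian_filter1d(x, smooth_sigma, axis=0, mode="nearest")
    fs = float(frame_rate)
    v = np.empty_like(x)
    a = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * (fs / 2.0)
    a[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) * fs * fs
    v[0], v[-1] = v[1], v[-2]
    a[0], a[-1] = a[1], a[-2]
    speed = np.linalg.norm(v, axis=1)
    return v, a, speed


@dataclass
class FightRecording:
    """Synchronized per-frame positions of two fish plus derived motion.

    Attributes
    ----------
    positions : (T, 2, 2) array
        Indexed [frame, fish, xy], cm.
    arena : ArenaConfig
    velocities, accelerations : (T, 2, 2) arrays
        Derived with :func:`derive_motion`.
    speeds : (T, 2) array
    """

    positions: np.ndarray
    arena: ArenaConfig
    smooth_sigma: float = 0.0
    velocities: np.ndarray = field(init=False, repr=False)
    accelerations: np.ndarray = field(init=False, repr=False)
    speeds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 3 or p.shape[1:] != (2, 2):
            raise ValueError("positions must have shape (T, 2, 2)")
        if p.shape[0] < 3:
            raise InsufficientDataError("a recording needs at least 3 frames")
        if not np.isfinite(p).all():
            raise BoundsError("non-finite positions")
        eps = 1e-9
        lo_ok = (p[..., 0] >= -eps) & (p[..., 1] >= -eps)
        hi_ok = (p[..., 0] <= self.arena.width + eps) & (
            p[..., 1] <= self.arena.height + eps)
        bad = ~(lo_ok & hi_ok)
        if bad.any():
            frames = np.unique(np.nonzero(bad)[0])[:10]
            raise BoundsError(
                f"positions outside arena at frames {frames.tolist()}")
        self.positions = p
        v = np.empty_like(p)
        a = np.empty_like(p)
        s = np.empty(p.shape[:2])
        for fish in (0, 1):
            v[:, fish], a[:, fish], s[:, fish] = derive_motion(
                p[:, fish], self.arena.frame_rate, self.smooth_sigma)
        self.velocities, self.accelerations, self.speeds = v, a, s

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def frame_rate(self) -> float:
        return self.arena.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def distances(self) -> np.ndarray:
        """Per-frame inter-fish centroid distance, cm."""
        return np.linalg.norm(
            self.positions[:, 0] - self.positions[:, 1], axis=1)

    def mirrored(self) -> "FightRecording":
        """Recording reflected about the arena's vertical mid-axis."""
        p = self.positions.copy()
        p[..., 0] = self.arena.width - p[..., 0]
        return FightRecording(p, self.arena, self.smooth_sigma)


@dataclass
class Ethogram:
    """Per-frame, per-fish attack annotation.

    ``scores`` holds the classifier attack score in [0, 1];
    ``labels`` is ``scores > threshold``; ``role`` is the index of the
    attacking fish (0 or 1) or :data:`ROLE_NONE`.  When both fish are
    labelled the attacker is the fish with the higher score (ties go to
    fish 0).
    """

    scores: np.ndarray
    labels: np.ndarray
    role: np.ndarray
    threshold: float = 0.5
    frame_rate: float = 20.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        self.role = np.asarray(self.role, dtype=np.int8)
        if self.scores.ndim != 2 or self.scores.shape[1] != 2:
            raise ValueError("scores must have shape (T, 2)")
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels and scores shapes differ")
        if self.role.shape != (self.scores.shape[0],):
            raise ValueError("role must have shape (T,)")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("scores must lie in [0, 1]")

    @classmethod
    def from_scores(cls, scores, threshold: float = 0.5,
                    frame_rate: float = 20.0) -> "Ethogram":
        """Threshold attack scores into labels and per-frame roles."""
        s = np.asarray(scores, dtype=float)
        labels = s > threshold
        role = np.full(s.shape[0], ROLE_NONE, dtype=np.int8)
        only0 = labels[:, 0] & ~labels[:, 1]
        only1 = labels[:, 1] & ~labels[:, 0]
        both = labels[:, 0] & labels[:, 1]
        role[only0] = 0
        role[only1] = 1
        # both labelled: the higher score is the attacker, ties -> fish 0
        role[both] = (s[both, 1] > s[both, 0]).astype(np.int8)
        return cls(s, labels, role, threshold, frame_rate)

    @classmethod
    def from_labels(cls, labels, role=None,
                    frame_rate: float = 20.0) -> "Ethogram":
        """Build an ethogram from hard labels (scores become 0/1)."""
        lab = np.asarray(labels, dtype=bool)
        if role is None:
            return cls.from_scores(lab.astype(float), 0.5, frame_rate)
        return cls(lab.astype(float), lab, role, 0.5, frame_rate)

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]

    def attack_any(self) -> np.ndarray:
        """Boolean series: is any fish attacking at each frame."""
        return self.labels.any(axis=1)
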