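"""Forcemaps: egocentric maps of speeding and turning acceleration.

For each frame the partner's position is expressed in the focal fish's
frame (focal at the origin, looking along +y, its right along +x) and
the focal acceleration is split into a component parallel to the
velocity (speeding) and one perpendicular to it, positive to the right
(turning).  Binning the partner position and averaging the two
components per bin yields the speeding and turning maps; the bin
occupancy, normalized over unmasked bins, gives the relative-position
density.

Wall effects are excluded per phase: symmetric-phase frames are kept
only when both fish are at least ``wall_margin`` from every wall;
asymmetric-phase frames only when both fish are at least
``corner_margin`` from every corner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ArenaConfig, Ethogram, FightRecording, ROLE_NONE
from .errors import DegenerateFrameError, EmptyResultError
from .simulate import SYMMETRIC, ASYMMETRIC


@dataclass(frozen=True)
class GridSpec:
    """Square binning grid, symmetric about the focal fish.

    ``extent_bl`` is the half-extent per axis in body lengths;
    ``n_bins`` the number of bins per axis.
    """

    extent_bl: float = 3.0
    n_bins: int = 21

    def edges(self, body_length: float) -> np.ndarray:
        e = self.extent_bl * body_length
        return np.linspace(-e, e, self.n_bins + 1)


@dataclass
class ForceMap:
    """Gridded mean speeding/turning forces and occupancy.

    Map arrays are indexed [ix, iy] following the bin edge arrays
    (x_rel = partner to the focal's right, y_rel = ahead).  Bins with
    fewer than ``min_count`` samples are masked and carry NaN forces;
    ``density`` is normalized to sum to 1 over unmasked bins.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    speeding: np.ndarray
    turning: np.ndarray
    count: np.ndarray
    density: np.ndarray
    mask: np.ndarray            # True where the bin is masked (too few)
    n_frames_used: int
    n_skipped_zero_speed: int

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


def to_focal_frame(focal_pos, focal_velocity, partner_pos):
    """Partner position in the focal frame (+y ahead, +x to the right)."""
    v = np.asarray(focal_velocity, float)
    speed = np.linalg.norm(v)
    if speed == 0:
        raise DegenerateFrameError("zero focal speed: heading undefined")
    vhat = v / speed
    rhat = np.array([vhat[1], -vhat[0]])
    rel = np.asarray(partner_pos, float) - np.asarray(focal_pos, float)
    return float(rel @ rhat), float(rel @ vhat)


def decompose_acceleration(v, a):
    """(speeding, turning) components of an acceleration vector.

    speeding = a . v_hat; turning = a . r_hat with r_hat the rightward
    unit vector, so positive turning means turning to the right.
    The components satisfy speeding**2 + turning**2 = |a|**2.
    """
    v = np.asarray(v, float)
    a = np.asarray(a, float)
    speed = np.linalg.norm(v)
    if speed == 0:
        raise DegenerateFrameError("zero speed: decomposition undefined")
    vhat = v / speed
    rhat = np.array([vhat[1], -vhat[0]])
    return float(a @ vhat), float(a @ rhat)


def wall_distance(positions, arena: ArenaConfig) -> np.ndarray:
    """Distance to the nearest wall for (.., 2) position arrays."""
    p = np.asarray(positions, float)
    return np.min(np.stack([p[..., 0], arena.width - p[..., 0],
                            p[..., 1], arena.height - p[..., 1]]), axis=0)


def corner_distance(positions, arena: ArenaConfig) -> np.ndarray:
    """Distance to the nearest corner for (.., 2) position arrays."""
    p = np.asarray(positions, float)
    corners = np.array([[0.0, 0.0], [arena.width, 0.0],
                        [0.0, arena.height], [arena.width, arena.height]])
    d = np.linalg.norm(p[..., None, :] - corners, axis=-1)
    return d.min(axis=-1)


def _phase_exclusion_mask(rec: FightRecording, phase: str) -> np.ndarray:
    """True where a frame passes the per-phase wall/corner exclusion."""
    if phase == SYMMETRIC:
        d = wall_distance(rec.positions, rec.arena)
        return (d >= rec.arena.wall_margin).all(axis=1)
    if phase == ASYMMETRIC:
        d = corner_distance(rec.positions, rec.arena)
        return (d >= rec.arena.corner_margin).all(axis=1)
    return np.ones(rec.n_frames, dtype=bool)


def compute_forcemap(rec: FightRecording, eth: Ethogram,
                     focal_role: str = "attacker",
                     phase: str = SYMMETRIC,
                     segmentation=None,
                     grid: GridSpec | None = None,
                     min_count: int = 20,
                     min_speed: float = 1e-9) -> ForceMap:
    """Forcemap of the attacker or defender in one fight phase.

    Frames contribute when an attack role is assigned, the frame lies
    in the requested phase (per ``segmentation``; ground-truth phase
    labels can be passed as a segmentation), the per-phase wall/corner
    exclusion passes and the focal fish has nonzero speed.
    """
    if focal_role not in ("attacker", "defender"):
        raise ValueError("focal_role must be 'attacker' or 'defender'")
    grid = grid or GridSpec()
    bl = rec.arena.body_length

    in_phase = np.ones(rec.n_frames, dtype=bool)
    if segmentation is not None:
        labels = (segmentation if isinstance(segmentation, np.ndarray)
                  else segmentation.frame_labels(rec.n_frames))
        in_phase = labels == phase
    has_role = eth.role != ROLE_NONE
    keep = in_phase & has_role & _phase_exclusion_mask(rec, phase)

    frames = np.nonzero(keep)[0]
    if frames.size == 0:
        raise EmptyResultError("no frames remain after phase exclusion")

    attacker = eth.role[frames].astype(int)
    focal = attacker if focal_role == "attacker" else 1 - attacker
    partner = 1 - focal

    fpos = rec.positions[frames, focal]
    ppos = rec.positions[frames, partner]
    fvel = rec.velocities[frames, focal]
    facc = rec.accelerations[frames, focal]

    speed = np.linalg.norm(fvel, axis=1)
    moving = speed > min_speed
    n_skipped = int((~moving).sum())
    frames, fpos, ppos, fvel, facc, speed = (
        frames[moving], fpos[moving], ppos[moving], fvel[moving],
        facc[moving], speed[moving])
    if frames.size == 0:
        raise EmptyResultError("no moving-focal frames remain")

    vhat = fvel / speed[:, None]
    rhat = np.stack([vhat[:, 1], -vhat[:, 0]], axis=1)
    rel = ppos - fpos
    x_rel = np.einsum("ij,ij->i", rel, rhat)
    y_rel = np.einsum("ij,ij->i", rel, vhat)
    speeding = np.einsum("ij,ij->i", facc, vhat)
    turning = np.einsum("ij,ij->i", facc, rhat)

    edges = grid.edges(bl)
    count, _, _ = np.histogram2d(x_rel, y_rel, bins=(edges, edges))
    sp_sum, _, _ = np.histogram2d(x_rel, y_rel, bins=(edges, edges),
                                  weights=speeding)
    tu_sum, _, _ = np.histogram2d(x_rel, y_rel, bins=(edges, edges),
                                  weights=turning)
    mask = count < min_count
    with np.errstate(invalid="ignore", divide="ignore"):
        sp = np.where(mask, np.nan, sp_sum / np.maximum(count, 1))
        tu = np.where(mask, np.nan, tu_sum / np.maximum(count, 1))
    unmasked_total = count[~mask].sum()
    density = np.where(mask, 0.0,
                       count / unmasked_total if unmasked_total else 0.0)
    return ForceMap(edges, edges.copy(), sp, tu, count.astype(int),
                    density, mask, int(frames.size), n_skipped)
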