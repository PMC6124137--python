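"""Identity resolution through collisions.

When two fish touch, a tracker sees a single merged blob.  The blob is
split into two candidate centroids with a two-component Gaussian
mixture, and identities are propagated through the collision by greedy
acceleration minimization: at each frame, holding the previous two
identified frames fixed, the assignment giving the smaller summed
second-difference magnitude over both trajectories is chosen.  The
identities entering and leaving the collision are known (anchors); if
the greedy pass ends in a state that contradicts the post-anchor the
interval is flagged rather than backtracked.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.mixture import GaussianMixture

from .errors import ConvergenceError, InsufficientDataError

STATUS_OK = "ok"
STATUS_ANCHOR_MISMATCH = "anchor-mismatch"


@dataclass
class CollisionInterval:
    """Unidentified candidate pairs flanked by identified anchors.

    ``pre_anchor``: (2, 2, 2) identified positions of the two frames
    before the collision (frame, fish, xy).  ``candidates``: (L, 2, 2)
    unordered coordinate pairs per collision frame.  ``post_anchor``:
    (2, 2) identified positions of the frame after the collision.
    """

    pre_anchor: np.ndarray
    candidates: np.ndarray
    post_anchor: np.ndarray

    def __post_init__(self) -> None:
        self.pre_anchor = np.asarray(self.pre_anchor, float)
        self.candidates = np.asarray(self.candidates, float).reshape(-1, 2, 2)
        self.post_anchor = np.asarray(self.post_anchor, float)
        if self.pre_anchor.shape != (2, 2, 2):
            raise ValueError("pre_anchor must have shape (2, 2, 2)")
        if self.post_anchor.shape != (2, 2):
            raise ValueError("post_anchor must have shape (2, 2)")

    @property
    def n_frames(self) -> int:
        return self.candidates.shape[0]


@dataclass
class IdentityAssignment:
    """Resolved per-frame identities for one collision interval.

    ``perm[t] == 0`` keeps the candidate order (candidate 0 is fish 0);
    ``perm[t] == 1`` swaps it.  ``positions`` is the identified (L, 2, 2)
    array.  ``status`` is ``"ok"`` or ``"anchor-mismatch"`` when the
    greedy pass ends in a state that contradicts the post-anchor.
    """

    perm: np.ndarray
    positions: np.ndarray
    status: str
    total_acceleration: float


def split_merged_blob(points, seed: int = 0, max_iter: int = 200):
    """Split a merged detection into two centroids with a 2-GMM.

    Parameters
    ----------
    points : (N, 2) array, N >= 4
        Pixel/coordinate samples of the merged blob.

    Returns
    -------
    centroids : (2, 2) array of component means
    labels : (N,) component index per sample
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    if pts.shape[0] < 4:
        raise InsufficientDataError("need at least 4 points to split a blob")
    gm = GaussianMixture(n_components=2, covariance_type="spherical",
                         init_params="k-means++", n_init=1,
                         max_iter=max_iter, random_state=seed)
    labels = gm.fit_predict(pts)
    if not gm.converged_:
        raise ConvergenceError(f"EM did not converge in {max_iter} iterations")
    return gm.means_.copy(), labels


def _step_cost(p2, p1, cand, perm: int) -> float:
    """Summed |x_t - 2 x_{t-1} + x_{t-2}| over both fish for one step."""
    c = cand[::-1] if perm else cand
    return float(np.linalg.norm(c - 2.0 * p1 + p2, axis=1).sum())


def resolve_identities(interval: CollisionInterval) -> IdentityAssignment:
    """Greedy acceleration-minimizing identity propagation.

    Walks the interval frame by frame, choosing at each frame the
    candidate assignment with the lower total second-difference
    magnitude given the previous two identified frames (ties keep the
    previous frame's ordering).  The terminal state is checked against
    the post-anchor; a conflict yields ``status="anchor-mismatch"``
    with the best-effort assignment.
    """
    L = interval.n_frames
    p2, p1 = interval.pre_anchor[0], interval.pre_anchor[1]
    perm = np.zeros(L, dtype=np.int8)
    positions = np.empty((L, 2, 2))
    prev_perm = 0
    total = 0.0
    for t in range(L):
        cand = interval.candidates[t]
        c_keep = _step_cost(p2, p1, cand, 0)
        c_swap = _step_cost(p2, p1, cand, 1)
        if c_keep < c_swap:
            choice = 0
        elif c_swap < c_keep:
            choice = 1
        else:
            choice = prev_perm
        perm[t] = choice
        positions[t] = cand[::-1] if choice else cand
        total += min(c_keep, c_swap)
        p2, p1 = p1, positions[t]
        prev_perm = choice
    # terminal consistency: would the greedy step onto the post-anchor
    # prefer the anchored identities or their swap?
    c_anchor = _step_cost(p2, p1, interval.post_anchor, 0)
    c_swapped = _step_cost(p2, p1, interval.post_anchor, 1)
    status = STATUS_OK if c_anchor <= c_swapped else STATUS_ANCHOR_MISMATCH
    total += c_anchor
    return IdentityAssignment(perm, positions, status, total)


def resolve_identities_exhaustive(interval: CollisionInterval,
                                  max_frames: int = 12
                                  ) -> IdentityAssignment:
    """Globally optimal assignment by enumeration of all 2^L paths.

    Minimizes the summed second-difference magnitude over the whole
    interval including the transition onto the post-anchor.  Intended
    as an oracle and fallback for short intervals.
    """
    L = interval.n_frames
    if L > max_frames:
        raise InsufficientDataError(
            f"exhaustive search limited to {max_frames} frames, got {L}")
    best_perm, best_total, best_positions = None, np.inf, None
    for assignment in product((0, 1), repeat=L):
        p2, p1 = interval.pre_anchor[0], interval.pre_anchor[1]
        total = 0.0
        positions = np.empty((L, 2, 2))
        for t, choice in enumerate(assignment):
            cand = interval.candidates[t]
            total += _step_cost(p2, p1, cand, choice)
            positions[t] = cand[::-1] if choice else cand
            p2, p1 = p1, positions[t]
        total += _step_cost(p2, p1, interval.post_anchor, 0)
        if total < best_total:
            best_total = total
            best_perm = np.array(assignment, dtype=np.int8)
            best_positions = positions
    return IdentityAssignment(best_perm, best_positions, STATUS_OK,
                              best_total)


def resolver_accuracy(assignment, truth) -> float:
    """Fraction of collision frames with the correct identity.

    Both arguments are per-frame permutation codes (0 = candidate order
    kept, 1 = swapped), or :class:`IdentityAssignment` for the first.
    """
    if isinstance(assignment, IdentityAssignment):
        assignment = assignment.perm
    a = np.asarray(assignment)
    b = np.asarray(truth)
    if a.shape != b.shape:
        raise ValueError("assignment and truth lengths differ")
    if a.size == 0:
        return 1.0
    return float(np.mean(a == b))
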