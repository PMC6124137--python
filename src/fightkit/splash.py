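"""Splash manoeuvre quantification.

A splash is a sub-second manoeuvre in which, at contact, one or both
fish reverse heading with a violent acceleration and the pair is
propelled several body lengths apart.  The orientation-change index of
an event is the cosine of the angle between the heading shortly before
and shortly after the event: -1 for a full reversal, +1 for an
unchanged heading.

Real splashes are rare and short, so in practice they may be annotated
by hand; :func:`detect_splashes` provides an automatic heuristic built
from the defining phenomenology (contact, acceleration spike, heading
reversal, rapid separation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FightRecording
from .errors import DegenerateFrameError, EmptyResultError


@dataclass(frozen=True)
class SplashParams:
    """Detector thresholds (defaults follow the defining phenomenology).

    ``accel_threshold`` defaults to ten times the 128 cm/s^2
    high-intensity burst threshold.  Headings are taken
    ``heading_lag_frames`` before and after the event frame.
    """

    contact_dist_bl: float = 0.5
    accel_threshold: float = 1280.0
    reversal_index_max: float = -0.5
    heading_lag_frames: int = 2
    separation_bl: float = 2.0
    separation_window_s: float = 1.0
    refractory_s: float = 1.0


@dataclass
class SplashEvent:
    """One detected (or annotated) splash manoeuvre."""

    frame: int
    heading_pre: np.ndarray      # (2, 2) unit headings before the event
    heading_post: np.ndarray     # (2, 2) unit headings after
    per_fish_index: np.ndarray   # (2,) orientation-change index per fish
    orientation_change_index: float  # event index = mean over the pair


def orientation_change_index(heading_pre, heading_post) -> float:
    """Cosine of the heading change: -1 = 180 deg reversal, 1 = unchanged."""
    a = np.asarray(heading_pre, float)
    b = np.asarray(heading_post, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateFrameError("zero-length heading")
    return float(a @ b / (na * nb))


def detect_splashes(rec: FightRecording,
                    params: SplashParams | None = None) -> list:
    """Heuristic splash detector.

    An event is reported at frame t when the inter-fish distance is
    below the contact threshold, either fish's acceleration magnitude
    exceeds ``accel_threshold``, the pair's mean orientation-change
    index across the event is below ``reversal_index_max``, and the
    fish separate to at least ``separation_bl`` body lengths within
    ``separation_window_s``.  Events within the refractory window of an
    accepted event are suppressed.
    """
    p = params or SplashParams()
    bl = rec.arena.body_length
    fs = rec.frame_rate
    lag = p.heading_lag_frames
    dist = rec.distances()
    acc_mag = np.linalg.norm(rec.accelerations, axis=2).max(axis=1)
    candidates = np.nonzero((dist < p.contact_dist_bl * bl)
                            & (acc_mag > p.accel_threshold))[0]
    sep_w = int(round(p.separation_window_s * fs))
    refractory = int(round(p.refractory_s * fs))
    events: list[SplashEvent] = []
    last = -np.inf
    for t in candidates:
        if t - last < refractory:
            continue
        if t - lag < 0 or t + lag >= rec.n_frames:
            continue
        pre = rec.velocities[t - lag]
        post = rec.velocities[t + lag]
        if (np.linalg.norm(pre, axis=1) == 0).any() or \
                (np.linalg.norm(post, axis=1) == 0).any():
            continue
        idx = np.array([orientation_change_index(pre[f], post[f])
                        for f in (0, 1)])
        event_idx = float(idx.mean())
        if event_idx >= p.reversal_index_max:
            continue
        future = dist[t + 1:t + 1 + sep_w]
        if future.size == 0 or future.max() < p.separation_bl * bl:
            continue
        pre_u = pre / np.linalg.norm(pre, axis=1, keepdims=True)
        post_u = post / np.linalg.norm(post, axis=1, keepdims=True)
        events.append(SplashEvent(int(t), pre_u, post_u, idx, event_idx))
        last = t
    return events


@dataclass
class AlignedSplashTraces:
    """Mean event-aligned traces; the event occurs at time 0."""

    time_s: np.ndarray
    contact_probability: np.ndarray
    acceleration: np.ndarray     # mean over both fish, cm/s^2
    distance: np.ndarray         # inter-fish distance, cm
    n_events: int


def splash_aligned_traces(rec: FightRecording, events,
                          window_s: float = 1.0,
                          contact_dist_bl: float = 0.5
                          ) -> AlignedSplashTraces:
    """Pointwise mean traces across events aligned at the event frame.

    Events whose +/- window would leave the recording are dropped;
    an empty usable set raises :class:`EmptyResultError`.
    """
    w = int(round(window_s * rec.frame_rate))
    frames = [e.frame if isinstance(e, SplashEvent) else int(e)
              for e in events]
    frames = [f for f in frames if f - w >= 0 and f + w < rec.n_frames]
    if not frames:
        raise EmptyResultError("no usable splash events")
    dist = rec.distances()
    acc = np.linalg.norm(rec.accelerations, axis=2).mean(axis=1)
    contact = dist < contact_dist_bl * rec.arena.body_length
    n = 2 * w + 1
    c_sum = np.zeros(n)
    a_sum = np.zeros(n)
    d_sum = np.zeros(n)
    for f in frames:
        sl = slice(f - w, f + w + 1)
        c_sum += contact[sl]
        a_sum += acc[sl]
        d_sum += dist[sl]
    m = len(frames)
    t = (np.arange(n) - w) / rec.frame_rate
    return AlignedSplashTraces(t, c_sum / m, a_sum / m, d_sum / m, m)
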