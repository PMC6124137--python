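"""Fight-level kinematic and assessment statistics.

Windowed attack fractions and burst fractions, exact binomial tests,
Pearson correlation, fight-duration regression, the dominance rule
(more than 90% of attacks over the preceding 4 minutes), phase
segmentation into pre-fight / symmetric / asymmetric periods, and
attack-aligned velocity/acceleration waveforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import Ethogram, FightRecording
from .errors import (CollinearityError, EmptyResultError,
                     InsufficientDataError, UndefinedCorrelationError)
from .simulate import PRE_FIGHT, SYMMETRIC, ASYMMETRIC, _runs


@dataclass(frozen=True)
class BurstConfig:
    """High-intensity acceleration bout threshold (strict >), cm/s^2."""

    threshold: float = 128.0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")


@dataclass
class PhaseSegmentation:
    """Ordered, disjoint labelled intervals covering a recording."""

    intervals: list  # [(start_frame, end_frame_exclusive, label)]

    def frame_labels(self, n_frames: int | None = None) -> np.ndarray:
        n = n_frames or self.intervals[-1][1]
        out = np.full(n, "unresolved", dtype="<U10")
        for start, end, label in self.intervals:
            out[start:end] = label
        return out

    def frames_for(self, label: str) -> np.ndarray:
        parts = [np.arange(s, e) for s, e, lab in self.intervals
                 if lab == label]
        return np.concatenate(parts) if parts else np.array([], dtype=int)


def _window_slices(n_frames: int, window_frames: int):
    for start in range(0, n_frames, window_frames):
        yield start, min(start + window_frames, n_frames)


def attack_fraction_series(eth: Ethogram, window_s: float = 120.0
                           ) -> pd.DataFrame:
    """Attack fractions per non-overlapping time window.

    Per fish: attacking frames / window frames.  The total fraction is
    the sum of the two individual fractions (it may exceed 1 when both
    fish attack simultaneously).  A trailing partial window is
    reported with its own length.
    """
    w = max(int(round(window_s * eth.frame_rate)), 1)
    rows = []
    for start, end in _window_slices(eth.n_frames, w):
        nf = end - start
        f1 = eth.labels[start:end, 0].mean() if nf else np.nan
        f2 = eth.labels[start:end, 1].mean() if nf else np.nan
        rows.append({"window_start_s": start / eth.frame_rate,
                     "n_frames": nf, "fish1": f1, "fish2": f2,
                     "total": f1 + f2})
    return pd.DataFrame(rows)


def burst_fraction_series(accel_magnitude, frame_rate: float,
                          cfg: BurstConfig | None = None,
                          window_s: float = 120.0) -> pd.DataFrame:
    """Fraction of frames per window with |a| strictly above threshold."""
    cfg = cfg or BurstConfig()
    a = np.abs(np.asarray(accel_magnitude, float))
    w = max(int(round(window_s * frame_rate)), 1)
    rows = []
    for start, end in _window_slices(a.size, w):
        rows.append({"window_start_s": start / frame_rate,
                     "n_frames": end - start,
                     "burst_fraction": float(
                         np.mean(a[start:end] > cfg.threshold))})
    return pd.DataFrame(rows)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise InsufficientDataError("pearson_r needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def exact_binomial_test(k: int, n: int, tail: str = "one",
                        p0: float = 0.5) -> float:
    """Exact binomial test by direct pmf summation.

    One-tailed: P(X >= k).  Two-tailed (doubling convention at
    p0 = 0.5): 2 * min(P(X >= k), P(X <= k)) capped at 1.  For
    p0 = 0.5 the tail sums are computed in exact integer arithmetic.
    """
    if not (isinstance(k, (int, np.integer)) and
            isinstance(n, (int, np.integer)) and 0 <= k <= n):
        raise ValueError("need integers 0 <= k <= n")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if p0 == 0.5:
        upper = sum(comb(n, i) for i in range(k, n + 1)) / (1 << n)
        lower = sum(comb(n, i) for i in range(0, k + 1)) / (1 << n)
    else:
        i = np.arange(n + 1)
        pmf = stats.binom.pmf(i, n, p0)
        upper = float(pmf[k:].sum())
        lower = float(pmf[:k + 1].sum())
    if tail == "one":
        return min(upper, 1.0)
    return min(2.0 * min(upper, lower), 1.0)


@dataclass
class DurationRegression:
    """OLS fit of fight duration on the two contestants' sizes."""

    c_large: float
    c_small: float
    intercept: float
    p_large: float
    p_small: float
    p_intercept: float
    r_squared: float


def fight_duration_regression(size_large, size_small, durations
                              ) -> DurationRegression:
    """OLS with intercept: duration ~ c_large*L + c_small*S."""
    L = np.asarray(size_large, float)
    S = np.asarray(size_small, float)
    d = np.asarray(durations, float)
    if not (L.size == S.size == d.size):
        raise ValueError("input lengths differ")
    if L.size <= 3:
        raise InsufficientDataError(
            "need n > 3 for two slopes and an intercept")
    X = sm.add_constant(np.column_stack([L, S]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.OLS(d, X).fit()
        return DurationRegression(c_large=float(fit.params[1]),
                                  c_small=float(fit.params[2]),
                                  intercept=float(fit.params[0]),
                                  p_large=float(fit.pvalues[1]),
                                  p_small=float(fit.pvalues[2]),
                                  p_intercept=float(fit.pvalues[0]),
                                  r_squared=float(fit.rsquared))


def assign_dominance(eth: Ethogram, t: int, window_s: float = 240.0,
                     frac: float = 0.9):
    """Dominant fish over the window (t - window, t], if any.

    Returns the index of the fish delivering strictly more than
    ``frac`` of the attack-role frames in the window, or None.  Frames
    before the first complete window return None with a warning.
    """
    w = int(round(window_s * eth.frame_rate))
    if t + 1 < w:
        warnings.warn("dominance undefined before the first full window",
                      stacklevel=2)
        return None
    roles = eth.role[t - w + 1:t + 1]
    c0 = int(np.sum(roles == 0))
    c1 = int(np.sum(roles == 1))
    total = c0 + c1
    if total == 0:
        return None
    if c0 > frac * total:
        return 0
    if c1 > frac * total:
        return 1
    return None


def segment_phases(eth: Ethogram, min_total_fraction: float = 0.02,
                   window_s: float = 120.0,
                   dominance_window_s: float = 240.0,
                   dominance_frac: float = 0.9) -> PhaseSegmentation:
    """Label non-overlapping windows and merge them into phases.

    A window with total attack fraction below ``min_total_fraction``
    is quiet: pre-fight if no active window has occurred yet, else
    unresolved.  An active window is asymmetric when the dominance
    rule singles out one fish at the window's end, symmetric
    otherwise.
    """
    dom_w = int(round(dominance_window_s * eth.frame_rate))
    if eth.n_frames < dom_w:
        raise InsufficientDataError(
            "ethogram must span at least one dominance window")
    w = max(int(round(window_s * eth.frame_rate)), 1)
    labelled = []
    seen_active = False
    for start, end in _window_slices(eth.n_frames, w):
        total = eth.labels[start:end].mean(axis=0).sum()
        if total < min_total_fraction:
            label = PRE_FIGHT if not seen_active else "unresolved"
        else:
            seen_active = True
            t_end = end - 1
            if t_end + 1 >= dom_w:
                dom = assign_dominance(eth, t_end, dominance_window_s,
                                       dominance_frac)
            else:
                # before the first full dominance window, apply the
                # share rule to the whole available history
                roles = eth.role[:end]
                c0 = int(np.sum(roles == 0))
                c1 = int(np.sum(roles == 1))
                tot = c0 + c1
                dom = None
                if tot > 0:
                    if c0 > dominance_frac * tot:
                        dom = 0
                    elif c1 > dominance_frac * tot:
                        dom = 1
            label = ASYMMETRIC if dom is not None else SYMMETRIC
        labelled.append((start, end, label))
    merged = []
    for start, end, label in labelled:
        if merged and merged[-1][2] == label:
            merged[-1] = (merged[-1][0], end, label)
        else:
            merged.append((start, end, label))
    return PhaseSegmentation(merged)


def attack_events(eth: Ethogram, frames=None, min_frames: int = 3):
    """Maximal constant-attacker runs of attack frames.

    Returns a list of (start, end_inclusive, attacker).  Runs shorter
    than ``min_frames`` are discarded as annotation noise.
    """
    mask = np.zeros(eth.n_frames, dtype=bool)
    if frames is None:
        mask[:] = True
    else:
        mask[np.asarray(frames, int)] = True
    events = []
    for attacker in (0, 1):
        active = (eth.role == attacker) & mask
        for start, end in _runs(active):
            if end - start + 1 >= min_frames:
                events.append((start, end, attacker))
    events.sort()
    return events


@dataclass
class AlignedWaveforms:
    """Event-aligned mean kinematics of attacker and defender."""

    time_s: np.ndarray
    attacker_speed: np.ndarray
    defender_speed: np.ndarray
    attacker_accel: np.ndarray
    defender_accel: np.ndarray
    n_events: int
    median_duration_frames: int


def attack_aligned_average(rec: FightRecording, eth: Ethogram,
                           phase: str | None = None,
                           segmentation: PhaseSegmentation | None = None,
                           min_event_frames: int = 3) -> AlignedWaveforms:
    """Average attack waveform, aligned at attack onset (time 0).

    Traces run from onset to the median attack duration of the phase;
    at each time point the mean is over the events still in progress.
    """
    frames = None
    if phase is not None and segmentation is not None:
        frames = segmentation.frames_for(phase)
    events = attack_events(eth, frames, min_event_frames)
    if not events:
        raise EmptyResultError("no attack events in the requested phase")
    durations = np.array([e - s + 1 for s, e, _ in events])
    med = int(np.median(durations))
    acc_mag = np.linalg.norm(rec.accelerations, axis=2)
    att_v = np.zeros(med)
    dfn_v = np.zeros(med)
    att_a = np.zeros(med)
    dfn_a = np.zeros(med)
    counts = np.zeros(med)
    for start, end, attacker in events:
        m = min(med, end - start + 1, rec.n_frames - start)
        sl = slice(start, start + m)
        att_v[:m] += rec.speeds[sl, attacker]
        dfn_v[:m] += rec.speeds[sl, 1 - attacker]
        att_a[:m] += acc_mag[sl, attacker]
        dfn_a[:m] += acc_mag[sl, 1 - attacker]
        counts[:m] += 1
    counts = np.maximum(counts, 1)
    return AlignedWaveforms(time_s=np.arange(med) / rec.frame_rate,
                            attacker_speed=att_v / counts,
                            defender_speed=dfn_v / counts,
                            attacker_accel=att_a / counts,
                            defender_accel=dfn_a / counts,
                            n_events=len(events),
                            median_duration_frames=med)
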