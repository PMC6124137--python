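"""Attack classification from short egocentric trajectory windows.

A window of K+1 frames ending at frame t is mapped into a rigid frame
anchored at t - K: the origin is the joint centre of mass of the two
fish and the +x axis points from the focal fish to its partner.  The
four per-window series (focal positions, partner positions, focal
velocities, partner velocities) are transformed into this frame
(velocities by rotation only) and concatenated into a feature vector
of length 8*(K+1).  The construction removes global translational and
rotational variance while preserving chirality, so left and right
remain distinguishable.

A multilayer perceptron (two rectifier hidden layers, cross-entropy
loss) maps the feature vector to an attack probability.  Scoring a
recording evaluates the network twice per frame, once with each fish
as focal, and thresholding the two score series yields the ethogram
with dynamic attacker/defender roles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .core import Ethogram, FightRecording
from .errors import DegenerateFrameError, TrainingError, WindowError


@dataclass(frozen=True)
class FeatureConfig:
    """Egocentric window shape: lag K (window [t-K, t]) in frames."""

    K: int = 10
    include_velocities: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def n_features(self) -> int:
        per_frame = 8 if self.include_velocities else 4
        return per_frame * (self.K + 1)


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and training settings of the attack scorer."""

    hidden_sizes: tuple = (250, 250)
    epochs: int = 120
    learning_rate: float = 1e-3
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be > 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


def egocentric_feature_matrix(rec: FightRecording, focal: int,
                              cfg: FeatureConfig, frames=None):
    """Vectorized egocentric features for many frames at once.

    Parameters
    ----------
    frames : array of frame indices (all >= K); default ``K .. T-1``.

    Returns
    -------
    X : (m, n_features) array
        Rows for degenerate anchors (coincident fish at t - K) are
        zero-filled.
    valid : (m,) bool array marking non-degenerate rows.
    """
    K = cfg.K
    if frames is None:
        frames = np.arange(K, rec.n_frames)
    frames = np.asarray(frames, dtype=int)
    if frames.size and (frames.min() < K or frames.max() >= rec.n_frames):
        raise WindowError("frames must lie in [K, n_frames)")
    anchors = frames - K

    pf = rec.positions[:, focal]
    pp = rec.positions[:, 1 - focal]
    vf = rec.velocities[:, focal]
    vp = rec.velocities[:, 1 - focal]

    com = 0.5 * (pf[anchors] + pp[anchors])           # (m, 2)
    axis = pp[anchors] - pf[anchors]
    norm = np.linalg.norm(axis, axis=1)
    valid = norm > 1e-12
    safe = np.where(valid, norm, 1.0)
    ex = axis / safe[:, None]
    ey = np.stack([-ex[:, 1], ex[:, 0]], axis=1)      # right-handed

    idx = anchors[:, None] + np.arange(K + 1)[None, :]  # (m, K+1)

    def project(series, shift):
        w = series[idx]                                # (m, K+1, 2)
        if shift:
            w = w - com[:, None, :]
        xs = np.einsum("mkj,mj->mk", w, ex)
        ys = np.einsum("mkj,mj->mk", w, ey)
        return np.stack([xs, ys], axis=-1)             # (m, K+1, 2)

    parts = [project(pf, True), project(pp, True)]
    if cfg.include_velocities:
        parts += [project(vf, False), project(vp, False)]
    X = np.concatenate([p.reshape(len(frames), -1) for p in parts], axis=1)
    X[~valid] = 0.0
    return X, valid


def egocentric_features(rec: FightRecording, t: int, focal: int,
                        cfg: FeatureConfig) -> np.ndarray:
    """Feature vector for a single frame (raises on edge cases)."""
    if t < cfg.K:
        raise WindowError(f"frame {t} precedes the first full window "
                          f"(K={cfg.K})")
    X, valid = egocentric_feature_matrix(rec, focal, cfg, np.array([t]))
    if not valid[0]:
        raise DegenerateFrameError(
            f"fish coincide at anchor frame {t - cfg.K}")
    return X[0]


@dataclass
class AttackScorer:
    """Trained attack scorer: feature scaling + MLP forward pass.

    Weights are stored as plain arrays so the scorer is portable and
    independent of the training backend; ``score`` runs its own
    rectifier/logistic forward pass.
    """

    weights: list = field(repr=False)
    biases: list = field(repr=False)
    scale_mean: np.ndarray = field(repr=False)
    scale_std: np.ndarray = field(repr=False)
    mlp_config: MLPConfig = field(default_factory=MLPConfig)
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    def score(self, X) -> np.ndarray:
        """Attack probability in [0, 1] for each feature row."""
        h = (np.atleast_2d(np.asarray(X, float)) - self.scale_mean) \
            / self.scale_std
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        z = (h @ self.weights[-1] + self.biases[-1]).ravel()
        return expit(z)

    def save(self, path) -> str:
        """Write a portable weight archive (.npz) with JSON metadata."""
        meta = {"mlp": {"hidden_sizes": list(self.mlp_config.hidden_sizes),
                        "epochs": self.mlp_config.epochs,
                        "learning_rate": self.mlp_config.learning_rate,
                        "seed": self.mlp_config.seed,
                        "threshold": self.mlp_config.threshold},
                "features": {"K": self.feature_config.K,
                             "include_velocities":
                                 self.feature_config.include_velocities}}
        arrays = {"scale_mean": self.scale_mean, "scale_std": self.scale_std,
                  "meta": np.frombuffer(
                      json.dumps(meta).encode(), dtype=np.uint8)}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)
        return str(path)

    @classmethod
    def load(cls, path) -> "AttackScorer":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            n_layers = sum(1 for k in data.files if k.startswith("W"))
            weights = [data[f"W{i}"] for i in range(n_layers)]
            biases = [data[f"b{i}"] for i in range(n_layers)]
            return cls(weights, biases, data["scale_mean"],
                       data["scale_std"],
                       MLPConfig(tuple(meta["mlp"]["hidden_sizes"]),
                                 meta["mlp"]["epochs"],
                                 meta["mlp"]["learning_rate"],
                                 meta["mlp"]["seed"],
                                 meta["mlp"]["threshold"]),
                       FeatureConfig(meta["features"]["K"],
                                     meta["features"]["include_velocities"]))


def train_attack_classifier(X, y, mlp: MLPConfig | None = None,
                            feature_config: FeatureConfig | None = None
                            ) -> AttackScorer:
    """Fit the MLP attack scorer on labelled feature windows.

    Training is deterministic given ``mlp.seed``.  Raises
    :class:`TrainingError` if only one class is present.
    """
    mlp = mlp or MLPConfig()
    feature_config = feature_config or FeatureConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if np.unique(y).size < 2:
        raise TrainingError("training data contain a single class")
    scaler = StandardScaler().fit(X)
    net = MLPClassifier(hidden_layer_sizes=tuple(mlp.hidden_sizes),
                        activation="relu", solver="adam",
                        learning_rate_init=mlp.learning_rate,
                        max_iter=mlp.epochs, random_state=mlp.seed,
                        tol=1e-5, n_iter_no_change=15)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(scaler.transform(X), y)
    return AttackScorer([W.copy() for W in net.coefs_],
                        [b.copy() for b in net.intercepts_],
                        scaler.mean_.copy(), scaler.scale_.copy(),
                        mlp, feature_config)


def attack_scores(rec: FightRecording, scorer: AttackScorer,
                  cfg: FeatureConfig | None = None) -> np.ndarray:
    """Per-frame per-fish attack scores for a whole recording.

    Frames before the first complete window and degenerate frames
    score 0.
    """
    cfg = cfg or scorer.feature_config
    scores = np.zeros((rec.n_frames, 2))
    frames = np.arange(cfg.K, rec.n_frames)
    for focal in (0, 1):
        X, valid = egocentric_feature_matrix(rec, focal, cfg, frames)
        s = np.zeros(len(frames))
        if valid.any():
            s[valid] = scorer.score(X[valid])
        if not valid.all():
            warnings.warn(f"{(~valid).sum()} degenerate frames scored 0",
                          stacklevel=2)
        scores[frames, focal] = s
    return scores


def ethogram_from_scores(scores, threshold: float = 0.5,
                         frame_rate: float = 20.0) -> Ethogram:
    """Threshold score series into an ethogram with per-frame roles."""
    return Ethogram.from_scores(scores, threshold, frame_rate)


def score_recording(rec: FightRecording, scorer: AttackScorer,
                    threshold: float | None = None) -> Ethogram:
    """Convenience: scores plus thresholding in one call."""
    s = attack_scores(rec, scorer)
    thr = scorer.mlp_config.threshold if threshold is None else threshold
    return ethogram_from_scores(s, thr, rec.frame_rate)
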