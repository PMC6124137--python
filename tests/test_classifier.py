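import numpy as np
import pytest
from hypothesis import given, strategies as st

from fightkit.classifier import (AttackScorer, FeatureConfig, MLPConfig,
                                 attack_scores, egocentric_features,
                                 ethogram_from_scores,
                                 train_attack_classifier)
from fightkit.core import ArenaConfig, FightRecording
from fightkit.errors import (DegenerateFrameError, TrainingError,
                             WindowError)


def _static_recording(p1, p2, n=15, arena=None):
    pos = np.empty((n, 2, 2))
    pos[:, 0] = p1
    pos[:, 1] = p2
    return FightRecording(pos, arena or ArenaConfig())


def _rotate(points, angle):
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return points @ R.T


class TestEgocentricFeatures:
    cfg = FeatureConfig(K=10)

    def test_static_pair_maps_to_unit_axis(self):
        # focal at (10,10), partner at (12,10): separation 2 cm, so in
        # the egocentric frame focal sits at (-1, 0), partner at (1, 0)
        rec = _static_recording([10.0, 10.0], [12.0, 10.0])
        f = egocentric_features(rec, 10, 0, self.cfg)
        K1 = self.cfg.K + 1
        focal = f[:2 * K1].reshape(K1, 2)
        partner = f[2 * K1:4 * K1].reshape(K1, 2)
        assert np.allclose(focal, [-1.0, 0.0])
        assert np.allclose(partner, [1.0, 0.0])

    def test_vertical_axis_pair_equals_hand_rotation(self):
        # partner straight above: the egocentric x-axis is global +y,
        # so the transform is a rotation by -90 degrees about the
        # centre of mass
        rec = _static_recording([10.0, 10.0], [10.0, 12.0])
        f = egocentric_features(rec, 10, 0, self.cfg)
        K1 = self.cfg.K + 1
        focal = f[:2 * K1].reshape(K1, 2)
        com = np.array([10.0, 11.0])
        expected = _rotate(np.array([10.0, 10.0]) - com, -np.pi / 2)
        assert np.allclose(focal, expected, atol=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        base = 12.0 + rng.normal(size=(15, 2, 2))
        arena = ArenaConfig(width=200.0, height=200.0)
        rec = FightRecording(base.copy(), arena)
        f_ref = egocentric_features(rec, 12, 0, self.cfg)
        for angle, shift in [(0.7, [30.0, 40.0]), (-2.1, [50.0, 10.0]),
                             (3.0, [100.0, 100.0])]:
            moved = _rotate(base.reshape(-1, 2) - 12.0,
                            angle).reshape(15, 2, 2)
            moved += 12.0 + np.asarray(shift)
            rec2 = FightRecording(moved, arena)
            f2 = egocentric_features(rec2, 12, 0, self.cfg)
            assert np.allclose(f2, f_ref, atol=1e-9)

    def test_reflection_changes_features(self):
        rng = np.random.default_rng(1)
        base = 12.0 + rng.normal(size=(15, 2, 2))
        arena = ArenaConfig(width=200.0, height=200.0)
        rec = FightRecording(base.copy(), arena)
        mirrored = base.copy()
        mirrored[..., 0] = 24.0 - mirrored[..., 0]
        rec2 = FightRecording(mirrored, arena)
        f1 = egocentric_features(rec, 12, 0, self.cfg)
        f2 = egocentric_features(rec2, 12, 0, self.cfg)
        assert not np.allclose(f1, f2, atol=1e-6)

    def test_frame_before_window_rejected(self):
        rec = _static_recording([10.0, 10.0], [12.0, 10.0])
        with pytest.raises(WindowError):
            egocentric_features(rec, 5, 0, self.cfg)

    def test_coincident_fish_rejected(self):
        rec = _static_recording([10.0, 10.0], [10.0, 10.0])
        with pytest.raises(DegenerateFrameError):
            egocentric_features(rec, 10, 0, self.cfg)


def _separable_dataset(n=400, K=10, seed=0):
    """Windows where 'attack' means fast approach toward the partner."""
    from fightkit.classifier import egocentric_feature_matrix

    rng = np.random.default_rng(seed)
    arena = ArenaConfig(width=200.0, height=200.0)
    X, y = [], []
    fcfg = FeatureConfig(K=K)
    for i in range(n):
        attack = i % 2 == 0
        speed = 15.0 if attack else 3.0
        start = rng.uniform(50.0, 150.0, size=2)
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        partner = start + direction * 20.0
        pos = np.empty((K + 1, 2, 2))
        toward = direction if attack else _rotate(direction, np.pi / 2)
        for t in range(K + 1):
            pos[t, 0] = start + toward * speed * t * 0.05
            pos[t, 1] = partner
        rec = FightRecording(pos, arena)
        feats, valid = egocentric_feature_matrix(rec, 0, fcfg,
                                                 np.array([K]))
        X.append(feats[0])
        y.append(int(attack))
    return np.array(X), np.array(y)


class TestTraining:
    def test_separable_data_learned_to_high_accuracy(self):
        X, y = _separable_dataset(400)
        Xte, yte = _separable_dataset(200, seed=1)
        scorer = train_attack_classifier(
            X, y, MLPConfig(hidden_sizes=(50, 50), epochs=80, seed=0))
        acc = ((scorer.score(Xte) > 0.5).astype(int) == yte).mean()
        assert acc >= 0.95

    def test_single_class_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(TrainingError):
            train_attack_classifier(X, np.zeros(10, int))

    def test_same_seed_gives_identical_weights(self):
        X, y = _separable_dataset(100)
        cfg = MLPConfig(hidden_sizes=(20,), epochs=30, seed=4)
        s1 = train_attack_classifier(X, y, cfg)
        s2 = train_attack_classifier(X, y, cfg)
        for W1, W2 in zip(s1.weights, s2.weights):
            assert np.array_equal(W1, W2)

    def test_zeroed_weights_score_half(self):
        X, y = _separable_dataset(100)
        scorer = train_attack_classifier(
            X, y, MLPConfig(hidden_sizes=(20,), epochs=10, seed=0))
        scorer.weights = [np.zeros_like(W) for W in scorer.weights]
        scorer.biases = [np.zeros_like(b) for b in scorer.biases]
        assert np.allclose(scorer.score(X), 0.5)

    def test_save_load_roundtrip(self, tmp_path):
        X, y = _separable_dataset(100)
        scorer = train_attack_classifier(
            X, y, MLPConfig(hidden_sizes=(20,), epochs=20, seed=0))
        path = tmp_path / "model.npz"
        scorer.save(path)
        back = AttackScorer.load(path)
        assert np.allclose(back.score(X), scorer.score(X))
        assert back.feature_config == scorer.feature_config


@pytest.fixture(scope="module")
def scorer():
    X, y = _separable_dataset(300)
    return train_attack_classifier(
        X, y, MLPConfig(hidden_sizes=(50,), epochs=60, seed=0))


class TestAttackScores:

    def test_scores_in_unit_interval_and_zero_before_window(
            self, scorer, short_recording):
        s = attack_scores(short_recording, scorer)
        assert s.shape == (short_recording.n_frames, 2)
        assert s.min() >= 0.0 and s.max() <= 1.0
        assert np.all(s[:scorer.feature_config.K] == 0.0)

    def test_swapping_fish_swaps_score_series(self, scorer,
                                              short_recording):
        s = attack_scores(short_recording, scorer)
        swapped = FightRecording(short_recording.positions[:, ::-1],
                                 short_recording.arena)
        s2 = attack_scores(swapped, scorer)
        assert np.allclose(s2, s[:, ::-1])

    def test_stationary_distant_pair_scores_low(self, scorer):
        rec = _static_recording([5.0, 5.0], [25.0, 20.0], n=30)
        s = attack_scores(rec, scorer)
        assert (s[10:] < 0.5).all()


class TestEthogramFromScores:
    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=(200, 2))
        low = ethogram_from_scores(scores, 0.3)
        high = ethogram_from_scores(scores, 0.7)
        assert np.all(high.labels <= low.labels)

    @given(thr=st.floats(0.05, 0.95))
    def test_labels_iff_score_above_threshold(self, thr):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=(50, 2))
        eth = ethogram_from_scores(scores, thr)
        assert np.array_equal(eth.labels, scores > thr)
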