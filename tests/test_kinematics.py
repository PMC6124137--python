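import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from fightkit.core import Ethogram, ROLE_NONE
from fightkit.errors import (CollinearityError, EmptyResultError,
                             InsufficientDataError,
                             UndefinedCorrelationError)
from fightkit.kinematics import (assign_dominance,
                                 attack_aligned_average,
                                 attack_fraction_series,
                                 burst_fraction_series,
                                 exact_binomial_test,
                                 fight_duration_regression, pearson_r,
                                 segment_phases)


def _eth_from_labels(labels, fs=20.0):
    return Ethogram.from_scores(np.asarray(labels, float), 0.5, fs)


class TestAttackFractions:
    def test_known_fraction_in_two_minute_window(self):
        labels = np.zeros((2400, 2))
        labels[:600, 0] = 1.0  # 600 of 2400 frames
        af = attack_fraction_series(_eth_from_labels(labels), 120.0)
        assert af.loc[0, "fish1"] == pytest.approx(0.25)
        assert af.loc[0, "fish2"] == 0.0
        assert af.loc[0, "total"] == pytest.approx(0.25)

    def test_both_attacking_gives_total_two(self):
        labels = np.ones((100, 2))
        af = attack_fraction_series(_eth_from_labels(labels), 5.0)
        assert af.loc[0, "total"] == pytest.approx(2.0)

    def test_trailing_partial_window_reports_own_length(self):
        labels = np.zeros((3000, 2))
        af = attack_fraction_series(_eth_from_labels(labels), 120.0)
        assert list(af["n_frames"]) == [2400, 600]


class TestBurstFractions:
    def test_strict_threshold(self):
        a = [100.0, 130.0, 50.0, 200.0, 128.0]
        bf = burst_fraction_series(a, frame_rate=1.0, window_s=5.0)
        assert bf.loc[0, "burst_fraction"] == pytest.approx(0.4)

    @pytest.mark.parametrize("values, expected", [
        ([10.0, 20.0, 100.0], 0.0),
        ([200.0, 300.0, 129.0], 1.0),
    ])
    def test_extremes(self, values, expected):
        bf = burst_fraction_series(values, frame_rate=1.0, window_s=3.0)
        assert bf.loc[0, "burst_fraction"] == expected


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_invariant_under_positive_affine_maps(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert pearson_r(a * x + b, y) == pytest.approx(pearson_r(x, y),
                                                        abs=1e-9)


class TestExactBinomial:
    def test_size_advantage_p_values(self):
        # 20 dominant outcomes out of 25: the exact upper tail is
        # 68406 / 2^25, printed as 0.002 one-tailed / 0.004 two-tailed
        p1 = exact_binomial_test(20, 25, "one")
        assert p1 == pytest.approx(68406 / 2 ** 25, rel=1e-12)
        assert round(p1, 3) == 0.002
        assert round(exact_binomial_test(20, 25, "two"), 3) == 0.004

    def test_all_successes_small_n(self):
        assert exact_binomial_test(5, 5, "one") == pytest.approx(0.03125)

    @given(n=st.integers(1, 30), frac=st.floats(0, 1))
    def test_matches_scipy_enumeration(self, n, frac):
        k = int(round(frac * n))
        ours = exact_binomial_test(k, n, "one")
        ref = sps.binomtest(k, n, 0.5, alternative="greater").pvalue
        assert ours == pytest.approx(ref, rel=1e-10)
        ours2 = exact_binomial_test(k, n, "two")
        ref2 = sps.binomtest(k, n, 0.5, alternative="two-sided").pvalue
        assert ours2 == pytest.approx(ref2, rel=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_test(6, 5)


class TestDurationRegression:
    def test_noiseless_coefficients_recovered(self):
        rng = np.random.default_rng(0)
        L = rng.uniform(3, 5, size=30)
        S = rng.uniform(2, 4, size=30)
        d = -0.2 * L + 0.05 * S + 3.0
        fit = fight_duration_regression(L, S, d)
        assert fit.c_large == pytest.approx(-0.2, abs=1e-9)
        assert fit.c_small == pytest.approx(0.05, abs=1e-9)
        assert fit.intercept == pytest.approx(3.0, abs=1e-9)

    def test_constant_duration_gives_zero_slopes(self):
        rng = np.random.default_rng(1)
        L = rng.uniform(3, 5, size=20)
        S = rng.uniform(2, 4, size=20)
        fit = fight_duration_regression(L, S, np.full(20, 7.0))
        assert fit.c_large == pytest.approx(0.0, abs=1e-9)
        assert fit.c_small == pytest.approx(0.0, abs=1e-9)

    def test_underdetermined_design_rejected(self):
        with pytest.raises(InsufficientDataError):
            fight_duration_regression([1, 2, 3], [1, 2, 3], [1, 2, 3])

    def test_collinear_design_rejected(self):
        L = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(CollinearityError):
            fight_duration_regression(L, 2 * L, L)


class TestDominance:
    fs = 20.0
    w = int(240 * 20)

    def _eth(self, n0, n1):
        role = np.full(self.w, ROLE_NONE, dtype=np.int8)
        role[:n0] = 0
        role[n0:n0 + n1] = 1
        labels = np.zeros((self.w, 2), bool)
        labels[role == 0, 0] = True
        labels[role == 1, 1] = True
        return Ethogram(labels.astype(float), labels, role, 0.5, self.fs)

    def test_clear_majority_is_dominant(self):
        assert assign_dominance(self._eth(95, 5), self.w - 1) == 0

    def test_85_percent_is_not_dominant(self):
        assert assign_dominance(self._eth(85, 15), self.w - 1) is None

    def test_exactly_90_percent_is_not_dominant(self):
        # the rule is strictly more than 90%
        assert assign_dominance(self._eth(90, 10), self.w - 1) is None

    def test_before_first_window_returns_none_with_warning(self):
        with pytest.warns(UserWarning):
            assert assign_dominance(self._eth(95, 5), 100) is None


class TestSegmentPhases:
    fs = 20.0

    def _minutes(self, m):
        return int(m * 60 * self.fs)

    def test_canonical_fight_shape_segments_in_order(self):
        # quiet opening, a few minutes of mutual attacks, then a long
        # one-sided period: pre-fight -> symmetric -> asymmetric
        n = self._minutes(60)
        rng = np.random.default_rng(0)
        role = np.full(n, ROLE_NONE, dtype=np.int8)
        sym = slice(self._minutes(24), self._minutes(28))
        role[sym] = rng.integers(0, 2, size=self._minutes(4))
        asym = slice(self._minutes(34), self._minutes(60))
        role[asym] = 0
        # thin the attack frames to realistic fractions
        keep = rng.random(n) < 0.3
        role[~keep] = ROLE_NONE
        labels = np.zeros((n, 2), bool)
        labels[role == 0, 0] = True
        labels[role == 1, 1] = True
        eth = Ethogram(labels.astype(float), labels, role, 0.5, self.fs)
        seg = segment_phases(eth)
        order = [lab for _, _, lab in seg.intervals]
        assert order[0] == "pre-fight"
        assert "symmetric" in order and "asymmetric" in order
        assert order.index("symmetric") < order.index("asymmetric")
        assert order[-1] == "asymmetric"

    def test_all_quiet_is_single_prefight(self):
        n = self._minutes(10)
        labels = np.zeros((n, 2))
        seg = segment_phases(_eth_from_labels(labels))
        assert seg.intervals == [(0, n, "pre-fight")]

    def test_one_sided_attacks_throughout_is_single_asymmetric(self):
        n = self._minutes(10)
        labels = np.zeros((n, 2))
        labels[:, 0] = 1.0
        seg = segment_phases(_eth_from_labels(labels))
        assert len(seg.intervals) == 1
        assert seg.intervals[0][2] == "asymmetric"


class TestAlignedWaveforms:
    def test_single_event_average_equals_trace(self, short_recording):
        n = short_recording.n_frames
        labels = np.zeros((n, 2), bool)
        labels[100:120, 0] = True
        role = np.full(n, ROLE_NONE, dtype=np.int8)
        role[100:120] = 0
        eth = Ethogram(labels.astype(float), labels, role, 0.5, 20.0)
        wf = attack_aligned_average(short_recording, eth)
        assert wf.n_events == 1
        assert wf.median_duration_frames == 20
        assert np.allclose(wf.attacker_speed,
                           short_recording.speeds[100:120, 0])
        assert np.allclose(wf.defender_speed,
                           short_recording.speeds[100:120, 1])

    def test_no_events_rejected(self, short_recording):
        n = short_recording.n_frames
        eth = _eth_from_labels(np.zeros((n, 2)))
        with pytest.raises(EmptyResultError):
            attack_aligned_average(short_recording, eth)

    def test_simulated_attacks_elevate_both_speeds(self, short_fight):
        rec, gt = short_fight
        eth = Ethogram.from_labels(gt.labels, gt.role)
        wf = attack_aligned_average(rec, eth)
        baseline = rec.speeds[gt.phase == "pre-fight"].mean()
        assert wf.attacker_speed.mean() > baseline
        assert wf.defender_speed.mean() > baseline
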