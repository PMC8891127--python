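"""Sagittal chain reconstruction, CoM and distance-from-stand."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sts_sonify.kinematics import (
    Anthropometry,
    CalibrationPair,
    calibrate,
    calibration_from_postures,
    chain_and_body_com,
    distance_from_stand,
    segment_com,
)
from sts_sonify.simulate import PatternSpec, PostureConfig, generate_motion
from sts_sonify.traces import MotionTrace

angles = st.floats(min_value=-179.0, max_value=179.0)


def _oracle_chain(th_s, th_t, th_h, anthro):
    """Independent forward-kinematics oracle using complex numbers:
    each segment is a phasor exp(i*theta) measured from vertical."""
    segs = [(anthro.shank, th_s), (anthro.thigh, th_t), (anthro.hat, th_h)]
    joint = 0j
    coms, weights = [], []
    for sp, th in segs:
        u = np.exp(1j * np.radians(th))  # real = y (up), imag = x (forward)
        coms.append(joint + u * sp.L * sp.D)
        joint = joint + u * sp.L
        weights.append(sp.w)
    w = np.array(weights) / np.sum(weights)
    c = np.dot(w, coms)
    return c.imag, c.real  # (x, y)


class TestSegmentCom:
    def test_vertical_segment(self):
        assert segment_com(0.0, (0.0, 0.0), 0.25, 0.4) == (0.0, pytest.approx(0.1))

    def test_horizontal_segment(self):
        x, y = segment_com(90.0, (0.0, 0.0), 0.25, 0.4)
        assert x == pytest.approx(0.1)
        assert y == pytest.approx(0.0, abs=1e-12)

    def test_hand_trig_oracle(self):
        # 0.1 + sin30 * 0.15 = 0.175 ; 0.2 + cos30 * 0.15 = 0.3299
        x, y = segment_com(30.0, (0.1, 0.2), 0.3, 0.5)
        assert x == pytest.approx(0.175)
        assert y == pytest.approx(0.3299, abs=1e-4)


class TestChainAndBodyCom:
    def test_vertical_stack(self):
        a = Anthropometry()
        state = chain_and_body_com(0.0, 0.0, 0.0, a)
        assert state.x_com == pytest.approx(0.0, abs=1e-15)
        w = a.weights
        y_expected = (
            w[0] * a.shank.L * a.shank.D
            + w[1] * (a.shank.L + a.thigh.L * a.thigh.D)
            + w[2] * (a.shank.L + a.thigh.L + a.hat.L * a.hat.D)
        )
        assert state.y_com == pytest.approx(y_expected)

    def test_horizontal_body_swaps_coordinates(self):
        a = Anthropometry()
        up = chain_and_body_com(0.0, 0.0, 0.0, a)
        flat = chain_and_body_com(90.0, 90.0, 90.0, a)
        assert flat.y_com == pytest.approx(0.0, abs=1e-12)
        assert flat.x_com == pytest.approx(float(up.y_com))

    def test_matches_independent_oracle_on_random_triples(self, rng):
        a = Anthropometry()
        for _ in range(1000):
            th = rng.uniform(-179, 179, 3)
            state = chain_and_body_com(*th, a)
            ox, oy = _oracle_chain(*th, a)
            assert abs(float(state.x_com) - ox) < 1e-12
            assert abs(float(state.y_com) - oy) < 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(th_s=angles, th_t=angles, th_h=angles)
    def test_chain_consistency(self, th_s, th_t, th_h):
        """knee = ankle + shank vector, hip = knee + thigh vector."""
        a = Anthropometry()
        state = chain_and_body_com(th_s, th_t, th_h, a)
        np.testing.assert_allclose(
            [state.knee[0], state.knee[1]],
            [np.sin(np.radians(th_s)) * a.shank.L,
             np.cos(np.radians(th_s)) * a.shank.L], atol=1e-12)
        np.testing.assert_allclose(
            [state.hip[0] - state.knee[0], state.hip[1] - state.knee[1]],
            [np.sin(np.radians(th_t)) * a.thigh.L,
             np.cos(np.radians(th_t)) * a.thigh.L], atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(th_s=angles, th_t=angles, th_h=angles)
    def test_com_inside_segment_com_hull(self, th_s, th_t, th_h):
        """The body CoM is a convex combination of the segment CoMs."""
        state = chain_and_body_com(th_s, th_t, th_h)
        xs = [c[0] for c in state.seg_com.values()]
        ys = [c[1] for c in state.seg_com.values()]
        assert min(xs) - 1e-12 <= state.x_com <= max(xs) + 1e-12
        assert min(ys) - 1e-12 <= state.y_com <= max(ys) + 1e-12


class TestDistanceFromStand:
    @pytest.fixture()
    def cal(self):
        return CalibrationPair(sit=(0.2, 0.5), stand=(0.05, 0.8))

    def test_unity_at_sit(self, cal):
        assert distance_from_stand(0.2, 0.5, cal) == pytest.approx(1.0)

    def test_zero_at_stand(self, cal):
        assert distance_from_stand(0.05, 0.8, cal) == pytest.approx(0.0)

    def test_half_at_midpoint(self, cal):
        assert distance_from_stand(0.125, 0.65, cal) == pytest.approx(0.5)

    def test_can_exceed_one_beyond_sit(self, cal):
        assert distance_from_stand(0.3, 0.3, cal) > 1.0

    def test_monotone_on_straight_path(self, cal):
        u = np.linspace(0, 1, 101)
        x = cal.sit[0] + u * (cal.stand[0] - cal.sit[0])
        y = cal.sit[1] + u * (cal.stand[1] - cal.sit[1])
        d = distance_from_stand(x, y, cal)
        assert np.all(np.diff(d) < 0)
        np.testing.assert_allclose(d, 1 - u, atol=1e-12)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            CalibrationPair(sit=(0.2, 0.5), stand=(0.2, 0.5))


class TestCalibrate:
    def _constant_trace(self, posture, n=500, jitter=0.0, rng=None):
        base = {
            "theta_shank": np.full(n, posture[0]),
            "theta_thigh": np.full(n, posture[1]),
            "theta_hat": np.full(n, posture[2]),
        }
        if jitter:
            for k in base:
                base[k] = base[k] + rng.normal(0, jitter, n)
        return MotionTrace(fs=100, **base)

    def test_constant_windows_match_posture_chain(self):
        p = PostureConfig()
        sit = self._constant_trace((p.sit_shank, p.sit_thigh, p.sit_hat))
        stand = self._constant_trace((p.stand_shank, p.stand_thigh,
                                      p.stand_hat))
        pair = calibrate(sit, stand)
        ref = calibration_from_postures(p)
        np.testing.assert_allclose(pair.sit, ref.sit, atol=1e-12)
        np.testing.assert_allclose(pair.stand, ref.stand, atol=1e-12)

    def test_noisy_windows_average_out(self, rng):
        p = PostureConfig()
        n, sd = 500, 1.0
        sit = self._constant_trace((p.sit_shank, p.sit_thigh, p.sit_hat),
                                   n=n, jitter=sd, rng=rng)
        stand = self._constant_trace(
            (p.stand_shank, p.stand_thigh, p.stand_hat), n=n, jitter=sd,
            rng=rng)
        pair = calibrate(sit, stand)
        ref = calibration_from_postures(p)
        # 1 deg of angle jitter moves the CoM < ~0.02 body lengths, and
        # averaging n samples shrinks it by sqrt(n)
        bound = 3 * 0.02 / np.sqrt(n)
        assert abs(pair.sit[0] - ref.sit[0]) < bound
        assert abs(pair.stand[1] - ref.stand[1]) < bound

    def test_identical_windows_rejected(self):
        p = PostureConfig()
        sit = self._constant_trace((p.sit_shank, p.sit_thigh, p.sit_hat))
        with pytest.raises(ValueError, match="coincide"):
            calibrate(sit, sit)


def test_distance_continuous_along_generated_motion(specs):
    """d decreases from ~1 to ~0 over a generated P1 rise with no jumps."""
    from sts_sonify.kinematics import body_com_trajectory

    m = generate_motion(specs["P1"])
    cal = calibration_from_postures()
    state = body_com_trajectory(m)
    d = distance_from_stand(state.x_com, state.y_com, cal)
    assert d[0] == pytest.approx(1.0, abs=0.01)
    assert d[-1] == pytest.approx(0.0, abs=0.01)
    assert np.max(np.abs(np.diff(d))) < 0.02  # no discontinuities
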