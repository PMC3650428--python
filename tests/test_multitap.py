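"""n-tap MAP inference: oracle equivalence, smoother identity, PSE solver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import (
    lowaccel_cost,
    lowspeed_cost,
    numeric_minimizer,
    random_sequence,
)
from saltation import (
    MeasurementSequence,
    ObserverParams,
    TwoTapMeasurement,
    map_percept_lowaccel,
    map_percept_lowspeed,
    rts_percept_lowspeed,
    tau_effect_pse,
    two_tap_posterior,
)

PARAMS = ObserverParams(sigma_v=10.0, sigma_s_default=1.0)


def preset_15tap(isi: float, sigma_s=1.0) -> MeasurementSequence:
    x = np.repeat([0.0, 5.0, 10.0], 5)
    return MeasurementSequence.from_taps(np.arange(15) * isi, x, sigma_s)


class TestMeasurementSequence:
    def test_rejects_unordered_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MeasurementSequence.from_taps([0.0, 0.2, 0.1], [0, 1, 2], 1.0)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError, match="sigma_s"):
            MeasurementSequence.from_taps([0.0, 0.1], [0, 1], 0.0)

    def test_intervals(self):
        m = MeasurementSequence.from_taps([0.0, 0.1, 0.4], [0, 1, 2], 1.0)
        assert np.allclose(m.intervals, [0.1, 0.3])


class TestLowSpeedMap:
    def test_single_tap_is_veridical(self):
        m = MeasurementSequence.from_taps([0.0], [4.2], 0.7)
        p = map_percept_lowspeed(m, 10.0)
        assert p.x_star[0] == 4.2
        assert p.sd[0] == 0.7

    def test_two_taps_match_joint_posterior(self, rng):
        for _ in range(20):
            m2 = TwoTapMeasurement(
                x1m=rng.uniform(0, 10),
                x2m=rng.uniform(0, 10),
                t=rng.uniform(0.02, 0.5),
                sigma_s1=rng.uniform(0.3, 2),
                sigma_s2=rng.uniform(0.3, 2),
            )
            joint = two_tap_posterior(m2, 10.0)
            m = MeasurementSequence(
                times=np.array([0.0, m2.t]),
                x_m=np.array([m2.x1m, m2.x2m]),
                sigma_s=np.array([m2.sigma_s1, m2.sigma_s2]),
            )
            p = map_percept_lowspeed(m, 10.0)
            assert np.allclose(p.x_star, joint.mean, atol=1e-12)
            assert np.allclose(p.sd**2, np.diag(joint.cov), atol=1e-12)

    def test_agrees_with_generic_numeric_minimizer(self, rng):
        for _ in range(50):
            m = random_sequence(rng, int(rng.integers(2, 16)))
            p = map_percept_lowspeed(m, 10.0)
            oracle = numeric_minimizer(lowspeed_cost, m, 10.0)
            assert np.allclose(p.x_star, oracle, atol=1e-6)

    def test_flat_prior_returns_measurements(self, rng):
        m = random_sequence(rng, 8)
        p = map_percept_lowspeed(m, 1e8)
        assert np.allclose(p.x_star, m.x_m, atol=1e-6)

    def test_fifteen_tap_near_veridical_at_slow_rate(self):
        p = map_percept_lowspeed(preset_15tap(0.3), 10.0)
        assert np.max(np.abs(p.x_star - preset_15tap(0.3).x_m)) < 0.5

    def test_fifteen_tap_hops_linearly_at_rabbit_rate(self):
        p = map_percept_lowspeed(preset_15tap(0.05), 10.0)
        assert np.all(np.diff(p.x_star[:10]) > 0)

    def test_chain_reaction_decays_away_from_jumps(self):
        # displacement magnitude falls off monotonically with distance
        # from the nearest 5-cm jump in the stimulus
        m = preset_15tap(0.05)
        p = map_percept_lowspeed(m, 10.0)
        err = np.abs(p.x_star - m.x_m)
        assert np.all(np.diff(err[:5]) > 0)  # taps 1-5: jump follows tap 5
        # taps 6-10 sit between both jumps: displacement decays toward the middle
        assert np.all(np.diff(err[5:8]) < 0)
        assert np.all(np.diff(err[7:10]) > 0)

    def test_attention_profile_shifts_percept_distally(self):
        uniform = map_percept_lowspeed(preset_15tap(0.02), 10.0)
        attended = map_percept_lowspeed(
            preset_15tap(0.02, sigma_s=np.repeat([1.0, 2.0, 0.5], 5)), 10.0
        )
        assert attended.x_star.mean() > uniform.x_star.mean() + 0.5
        # at a slow tap rate the same profile barely matters
        u3 = map_percept_lowspeed(preset_15tap(0.3), 10.0)
        a3 = map_percept_lowspeed(
            preset_15tap(0.3, sigma_s=np.repeat([1.0, 2.0, 0.5], 5)), 10.0
        )
        slow_change = np.max(np.abs(a3.x_star - u3.x_star))
        fast_change = np.max(np.abs(attended.x_star - uniform.x_star))
        assert slow_change < fast_change

    @given(shift=st.floats(-50, 50))
    def test_translation_equivariance(self, shift):
        m = preset_15tap(0.05)
        shifted = MeasurementSequence(
            times=m.times, x_m=m.x_m + shift, sigma_s=m.sigma_s
        )
        a = map_percept_lowspeed(m, 10.0).x_star
        b = map_percept_lowspeed(shifted, 10.0).x_star
        assert np.allclose(b - a, shift, atol=1e-8)


class TestSmootherIdentity:
    def test_rts_equals_tridiagonal_map(self, rng):
        # forward Kalman filter + RTS backward pass reproduces the exact
        # MAP solution of the chain, means and marginal sds alike
        for _ in range(50):
            m = random_sequence(rng, int(rng.integers(1, 21)))
            a = map_percept_lowspeed(m, 10.0)
            b = rts_percept_lowspeed(m, 10.0)
            assert np.allclose(a.x_star, b.x_star, atol=1e-8)
            assert np.allclose(a.sd, b.sd, atol=1e-8)

    def test_single_tap(self):
        m = MeasurementSequence.from_taps([0.0], [1.5], 0.4)
        p = rts_percept_lowspeed(m, 10.0)
        assert p.x_star[0] == 1.5


class TestLowAccelMap:
    def test_two_taps_reduce_to_low_speed(self, rng):
        m = random_sequence(rng, 2)
        a = map_percept_lowspeed(m, 10.0)
        b = map_percept_lowaccel(m, 10.0)
        assert np.allclose(a.x_star, b.x_star, atol=1e-12)

    def test_needs_two_taps(self):
        with pytest.raises(ValueError, match="at least 2"):
            map_percept_lowaccel(
                MeasurementSequence.from_taps([0.0], [1.0], 1.0), 10.0
            )

    def test_agrees_with_generic_numeric_minimizer(self, rng):
        for _ in range(50):
            m = random_sequence(rng, int(rng.integers(2, 16)))
            p = map_percept_lowaccel(m, 10.0)
            oracle = numeric_minimizer(lowaccel_cost, m, 10.0)
            assert np.allclose(p.x_star, oracle, atol=1e-6)

    def test_symmetric_three_taps_perceived_asymmetrically(self):
        # only the first pair is speed-penalized, so the second interval
        # is perceived as longer than the first even when they are equal
        m = MeasurementSequence.from_taps([0.0, 0.3, 0.6], [0.0, 3.0, 6.0], 1.0)
        p = map_percept_lowaccel(m, 10.0)
        l1 = p.x_star[1] - p.x_star[0]
        l2 = p.x_star[2] - p.x_star[1]
        assert l2 > l1

    def test_endpoint_overshoot_on_rapid_rabbit(self):
        m = preset_15tap(0.02)
        p = map_percept_lowaccel(m, 10.0)
        assert p.x_star[0] < m.x_m[0]  # starts below the first tap
        assert p.x_star[-1] > m.x_m[-1]  # ends above the last tap


class TestTauEffectPse:
    def test_equal_intervals_give_veridical_spacing(self):
        p = ObserverParams.from_tau(0.10)
        for mode in ("pairwise", "joint"):
            assert tau_effect_pse(3.0, 0.5, 0.5, p, mode=mode) == pytest.approx(
                6.0, abs=1e-6
            )

    def test_pairwise_closed_form_example(self):
        # frozen from bisection on the contraction equality condition
        p = ObserverParams.from_tau(0.10)
        assert tau_effect_pse(3.0, 0.5, 0.125, p) == pytest.approx(
            3.0 + 3.0 * 2.28 / 1.08, abs=1e-9
        )

    def test_pse_recedes_as_second_interval_shortens(self):
        p = ObserverParams.from_tau(0.10)
        t2s = np.linspace(0.1, 0.5, 9)
        x3s = [tau_effect_pse(3.0, 0.5, t2, p) for t2 in t2s]
        assert np.all(np.diff(x3s) < 0)

    def test_joint_mode_diagnostic_on_bad_bracket(self):
        p = ObserverParams.from_tau(0.10)
        with pytest.raises(ValueError, match="no sign change"):
            tau_effect_pse(3.0, 0.5, 0.5, p, mode="joint", bracket=(20.0, 30.0))

    def test_invalid_arguments(self):
        p = ObserverParams.from_tau(0.10)
        with pytest.raises(ValueError):
            tau_effect_pse(-1.0, 0.5, 0.5, p)
        with pytest.raises(ValueError):
            tau_effect_pse(3.0, 0.5, 0.5, p, mode="other")
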