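"""Unit and property tests of the mean-field dynamics primitives."""

import numpy as np
import pytest

from catcircuit import NetworkParams, TaskSpec
from catcircuit.circuit import (NetworkState, gating_step, gaussian_coupling,
                                ou_noise_step, recurrent_current,
                                ring_coupling_matrix, step_network,
                                transfer_rate, wrapped_angle_diff)
from catcircuit.plasticity import init_weights

P = NetworkParams()


class TestTransferRate:
    def test_removable_singularity_equals_inverse_curvature(self):
        # at a*I - b = 0 the limit of x / (1 - exp(-d x)) is 1/d
        assert transfer_rate(0.4, P) == pytest.approx(1.0 / P.d, rel=1e-9)

    @pytest.mark.parametrize("current, expected", [
        (0.6, 54.013218),   # closed form: x / (1 - e^(-d x)) with x = 54
        (0.2, 0.0132101),   # subthreshold tail, x = -54
    ])
    def test_closed_form_values(self, current, expected):
        assert transfer_rate(current, P) == pytest.approx(expected, rel=1e-4)

    def test_monotone_and_continuous_across_singularity(self):
        I = np.linspace(0.39, 0.41, 2001)
        r = transfer_rate(I, P)
        assert np.all(np.diff(r) > 0)
        assert np.max(np.abs(np.diff(r))) < 0.05  # no jump at x = 0

    def test_nonnegative_everywhere(self):
        assert np.all(transfer_rate(np.linspace(-1, 2, 301), P) >= 0)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            transfer_rate(np.nan, P)


class TestGaussianCoupling:
    def test_identical_angles_give_peak(self):
        assert gaussian_coupling(30.0, 30.0, 1.5, -0.5, 43.2) == pytest.approx(1.5)

    def test_one_sigma_separation(self):
        val = gaussian_coupling(0.0, 43.2, 1.5, -0.5, 43.2)
        assert val == pytest.approx(-0.5 + 2.0 * np.exp(-0.5), rel=1e-12)

    def test_wrapping(self):
        assert wrapped_angle_diff(10.0, 350.0) == pytest.approx(20.0)
        assert gaussian_coupling(10.0, 350.0, 1.0, 0.0, 43.2) == \
            pytest.approx(gaussian_coupling(0.0, 20.0, 1.0, 0.0, 43.2))


class TestRecurrentCurrent:
    def test_uniform_network(self):
        G = np.full((8, 8), 0.7)
        s = np.full(8, 0.3)
        np.testing.assert_allclose(recurrent_current(s, G), 0.21)

    def test_zero_activity(self):
        G = np.random.default_rng(0).random((5, 5))
        np.testing.assert_allclose(recurrent_current(np.zeros(5), G), 0.0)

    def test_three_unit_worked_case(self):
        G = np.array([[1.0, 1.0, 1.0]])
        assert recurrent_current(np.array([0.1, 0.2, 0.3]), G)[0] == \
            pytest.approx(0.2)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            recurrent_current(np.zeros(4), np.zeros((3, 3)))


class TestOUNoise:
    def test_deterministic_decay_without_noise(self):
        rng = np.random.default_rng(0)
        I = np.full(3, 0.5)
        out = ou_noise_step(I, 1.0, 2.0, 0.0, rng)
        np.testing.assert_allclose(out, 0.5 * np.exp(-0.5))

    def test_stationary_sd_and_autocorrelation(self):
        rng = np.random.default_rng(1)
        n = 200_000
        x = np.empty(n)
        I = np.zeros(1)
        for k in range(n):
            I = ou_noise_step(I, 1.0, 2.0, 0.009, rng)
            x[k] = I[0]
        assert np.std(x[1000:]) == pytest.approx(0.009, rel=0.03)
        lag = 2  # one correlation time
        r = np.corrcoef(x[1000:-lag], x[1000 + lag:])[0, 1]
        assert r == pytest.approx(np.exp(-1.0), abs=0.02)


class TestGatingStep:
    def test_fixed_point_for_constant_rate(self):
        s = 0.2
        for _ in range(5000):
            s = gating_step(s, 20.0, 1.0, P)
        gam_r_tau = P.gamma * 20.0 * (P.tau_s / 1000.0)
        assert s == pytest.approx(gam_r_tau / (1 + gam_r_tau), rel=1e-3)
        assert s == pytest.approx(0.4348, abs=2e-4)

    def test_pure_decay_matches_exponential(self):
        s = 0.5
        for _ in range(60):
            s = gating_step(s, 0.0, 1.0, P)
        assert s == pytest.approx(0.5 * np.exp(-1.0), rel=1e-3)

    def test_global_error_is_second_order_in_dt(self):
        # integrate decay over 60 ms with dt and dt/2; error ratio ~ 4
        def final(dt):
            s = 0.5
            for _ in range(int(60 / dt)):
                s = gating_step(s, 0.0, dt, P)
            return s
        exact = 0.5 * np.exp(-1.0)
        e1 = abs(final(2.0) - exact)
        e2 = abs(final(1.0) - exact)
        assert e1 / e2 == pytest.approx(4.0, rel=0.2)

    def test_stays_in_unit_interval_under_random_rates(self):
        rng = np.random.default_rng(3)
        s = rng.random(50)
        for _ in range(200):
            s = gating_step(s, rng.uniform(0, 200, 50), 1.0, P)
            assert np.all((0 <= s) & (s <= 1))


class TestStepNetwork:
    def _small(self):
        p = NetworkParams(n_sensory=16, n_assoc=16)
        rng = np.random.default_rng(0)
        w = init_weights(p, rng)
        state = NetworkState.zeros(p)
        ext = (np.zeros(16), np.zeros(16), np.zeros(2))
        return p, w, state, ext

    def test_deterministic_without_noise(self):
        p, w, state, ext = self._small()
        state.s_sensory[:] = 0.3
        a = step_network(state, w, ext, p, rng=None)
        b = step_network(state, w, ext, p, rng=None)
        np.testing.assert_array_equal(a.s_sensory, b.s_sensory)
        np.testing.assert_array_equal(a.s_dec, b.s_dec)

    def test_symmetric_decision_trajectories(self):
        p, w, state, ext = self._small()
        w.c_ad[:] = 0.5
        w.c_da[:] = 0.5
        state.s_assoc[:] = 0.4
        for _ in range(100):
            state = step_network(state, w, ext, p, rng=None)
        assert state.s_dec[0] == pytest.approx(state.s_dec[1], abs=1e-12)

    def test_gating_decays_without_input(self):
        p, w, state, ext = self._small()
        # silence all couplings so each population decays independently
        p = p.replace(J_plus_sens=1e-6, J_minus_sens=0.0,
                      J_plus_assoc=1e-6, J_minus_assoc=0.0,
                      g_max_sa=0.0, g_max_ad=0.0, g_max_da=0.0,
                      i_bg_sens=0.0, i_bg_assoc=0.0, i_bg_dec=0.0,
                      J_dec_self=0.0, J_dec_cross=0.0)
        state.s_sensory[:] = 0.8
        for _ in range(60):
            state = step_network(state, w, ext, p, rng=None)
        np.testing.assert_allclose(state.s_sensory, 0.8 * np.exp(-1.0), rtol=1e-3)

    def test_spontaneous_state_stationary(self):
        # 2 s of spontaneous activity at default backgrounds stays bounded
        p = NetworkParams(n_sensory=32, n_assoc=32)
        rng = np.random.default_rng(5)
        w = init_weights(p, rng)
        state = NetworkState.zeros(p)
        ext = (np.zeros(32), np.zeros(32), np.zeros(2))
        rates = []
        for k in range(2000):
            state = step_network(state, w, ext, p, rng=rng)
            if k > 500:
                rates.append(state.r_dec.max())
        rates = np.asarray(rates)
        assert np.all(np.isfinite(rates))
        assert rates.max() < 20.0  # below decision threshold at rest
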