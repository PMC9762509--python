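import math

import numpy as np
import pytest

from gatedrnn import NetworkParams, Trajectory, make_network, simulate
from gatedrnn.lyapunov import (
    CorrelatorSet,
    UnsupportedRegimeError,
    dmft_lambda_max,
    kaplan_yorke,
    lyapunov_spectrum,
    max_lyapunov,
    measure_correlators,
)
from gatedrnn.network import default_initial_state, steady_state_moments
from gatedrnn.spectra import empirical_spectrum, instantaneous_jacobian


class TestLyapunovSpectrum:
    def test_silent_network_relaxes_at_gate_and_tau_rates(self):
        # g_h = 0 makes the flow linear: rates -sigma_z(0), -1/tau_z, -1/tau_r
        p = NetworkParams(n_units=30, g_h=0.0, tau_z=0.7, tau_r=1.5, seed=1)
        net = make_network(p)
        # long tangent warm-up: the subspace split between the -1/2 and
        # -1/tau clusters aligns at the small spectral gap rate
        res = lyapunov_spectrum(net, k=35, t_total=80.0, t_transient=5.0,
                                warmup_blocks=60)
        jac = instantaneous_jacobian(net, (np.zeros(30),) * 3)
        expected = np.sort(empirical_spectrum(jac).real)[::-1][:35]
        assert np.abs(res.exponents - expected).max() < 1e-3

    def test_chaotic_point_has_positive_lambda_max(self):
        net = make_network(NetworkParams(n_units=300, g_h=3.0, alpha_r=2.0, seed=2))
        lam = max_lyapunov(net, t_total=150.0, t_transient=50.0)
        assert lam > 0.02

    def test_spectrum_flattens_with_switchlike_update_gate(self):
        counts = []
        for az in (0.0, 10.0, 30.0):
            p = NetworkParams(n_units=250, g_h=3.0, alpha_z=az, seed=3)
            res = lyapunov_spectrum(make_network(p), k=30, t_total=150.0,
                                    t_transient=50.0)
            counts.append(int(np.sum(np.abs(res.exponents) < 0.05)))
        assert counts[0] < counts[1] <= counts[2]

    def test_reorthonormalization_interval_invariance(self):
        p = NetworkParams(n_units=150, g_h=3.0, alpha_r=2.0, seed=4)
        net = make_network(p)
        init = default_initial_state(net)
        a = lyapunov_spectrum(net, k=10, t_total=180.0, t_transient=30.0,
                              reorth_interval=1.0, initial_state=init)
        b = lyapunov_spectrum(net, k=10, t_total=180.0, t_transient=30.0,
                              reorth_interval=0.5, initial_state=init)
        assert np.abs(a.exponents - b.exponents).max() < 0.01

    def test_full_spectrum_sum_equals_mean_jacobian_trace(self):
        p = NetworkParams(n_units=60, g_h=2.5, alpha_z=1.0, alpha_r=1.0, seed=5)
        net = make_network(p)
        init = default_initial_state(net)
        res = lyapunov_spectrum(net, k=180, t_total=40.0, t_transient=10.0,
                                initial_state=init, warmup_blocks=0)
        traj = simulate(net, t_final=40.0, initial_state=init, record_every=20)
        start = np.searchsorted(traj.times, 10.0)
        traces = [np.trace(instantaneous_jacobian(net, (traj.h[i], traj.z[i], traj.r[i])))
                  for i in range(start, traj.n_samples)]
        total = res.exponents.sum()
        assert abs(total - np.mean(traces)) / abs(np.mean(traces)) < 0.02

    def test_invalid_arguments_rejected(self):
        net = make_network(NetworkParams(n_units=10, g_h=1.0, seed=1))
        with pytest.raises(ValueError):
            lyapunov_spectrum(net, k=31, t_total=10.0, t_transient=1.0)
        with pytest.raises(ValueError):
            lyapunov_spectrum(net, k=5, t_total=1.0, t_transient=5.0)


class TestKaplanYorke:
    def test_point_attractor_has_dimension_zero(self):
        assert kaplan_yorke(np.array([-0.1, -0.2])) == 0.0

    def test_direct_evaluation(self):
        assert kaplan_yorke(np.array([0.5, -1.0])) == pytest.approx(1.5)

    def test_needs_enough_exponents(self):
        with pytest.raises(ValueError, match="more exponents"):
            kaplan_yorke(np.array([0.5, 0.1]))

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_yorke(np.array([0.1, 0.5]))

    def test_dimension_rises_with_output_gate_gain(self):
        dims = []
        for ar in (0.0, 2.0, 6.0):
            p = NetworkParams(n_units=250, g_h=3.0, alpha_r=ar, seed=6)
            res = lyapunov_spectrum(make_network(p), k=40, t_total=150.0,
                                    t_transient=50.0)
            dims.append(res.ky_dimension)
        assert dims[0] < dims[1] < dims[2]


class TestCorrelators:
    def _white_noise_traj(self, rng, n=200, steps=500):
        p = NetworkParams(n_units=n, g_h=1.0)
        mk = lambda: rng.normal(0, 1, (steps, n))
        return Trajectory(times=np.arange(steps) * 0.05, h=mk(), z=mk(), r=mk(),
                          dt=0.05, params=p)

    def test_white_noise_has_no_temporal_structure(self, rng):
        traj = self._white_noise_traj(rng)
        corr = measure_correlators(traj, max_lag=2.0, burn_in=0.0)
        assert abs(corr.C["h"][0] - 1.0) < 0.02
        assert np.abs(corr.C["h"][1:]).max() < 0.01  # ~3 standard errors

    def test_zero_lag_matches_second_moment(self, chaotic_traj):
        corr = measure_correlators(chaotic_traj, max_lag=5.0, burn_in=0.5)
        mom = steady_state_moments(chaotic_traj, burn_in_fraction=0.5)
        assert corr.C["h"][0] == pytest.approx(mom.h2, rel=1e-10)

    def test_chaotic_autocorrelation_decays(self, chaotic_traj):
        # weak chaos decorrelates slowly: check monotone decay toward a
        # plateau (within estimation noise), not a fixed decay fraction
        corr = measure_correlators(chaotic_traj, max_lag=8.0, burn_in=0.5)
        c = corr.C["h"]
        assert c[0] >= max(c) - 1e-5
        assert np.all(np.diff(c) <= 1e-5)
        assert c[-1] < 0.97 * c[0]

    def test_window_precondition(self, chaotic_traj):
        with pytest.raises(Exception):
            measure_correlators(chaotic_traj, max_lag=50.0, burn_in=0.9)

    def test_symmetric_view_is_even(self, chaotic_traj):
        corr = measure_correlators(chaotic_traj, max_lag=5.0, burn_in=0.5)
        tau, c = corr.symmetric("phi")
        assert np.allclose(c, c[::-1])
        assert tau[0] == -tau[-1]


def _const_correlators(g, n_lags=101, dt_lag=0.4, beta_z=0.0):
    """Fixed-point correlators: constant in lag (the state does not move)."""
    p = NetworkParams(n_units=2, g_h=g, beta_z=beta_z)
    ones = np.ones(n_lags)
    C = {"h": ones * 0.0, "phi": ones * 0.0, "dphi": ones * g * g,
         "sz": ones * 0.25, "dsz": ones * 0.0, "sr": ones * 0.25,
         "dsr": ones * 0.0, "phisr": ones * 0.0}
    return CorrelatorSet(lags=np.arange(n_lags) * dt_lag, C=C,
                         window=n_lags * dt_lag, params=p)


class TestDmftLambdaMax:
    @pytest.mark.parametrize("g", [1.5, 2.5, 3.0])
    def test_zero_fp_closed_form(self, g):
        # constant C_phi' = g^2 gives kappa = g/4 - 1/2 (the spectral edge)
        kap = dmft_lambda_max(_const_correlators(g))
        assert kap == pytest.approx(g / 4 - 0.5, abs=0.02)

    def test_subcritical_sign(self):
        assert dmft_lambda_max(_const_correlators(1.5)) < 0

    def test_refuses_sensitive_update_gate(self, chaotic_traj):
        corr = measure_correlators(chaotic_traj, max_lag=5.0, burn_in=0.5)
        p = chaotic_traj.params.replace(alpha_z=2.0)
        with pytest.raises(UnsupportedRegimeError):
            dmft_lambda_max(corr, p)

    def test_chaotic_state_prediction_is_positive_and_below_fp_value(self,
                                                                     chaotic_traj):
        corr = measure_correlators(chaotic_traj, max_lag=14.0, burn_in=0.25)
        kap = dmft_lambda_max(corr)
        assert 0.0 < kap < 3.0 / 4 - 0.5  # decay of C_phi' lowers the edge
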