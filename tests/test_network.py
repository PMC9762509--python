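import math

import numpy as np
import pytest

from gatedrnn import (
    AnalysisError,
    NetworkParams,
    Trajectory,
    is_stationary,
    make_network,
    simulate,
    steady_state_moments,
)
from gatedrnn.mft import solve_fixed_point
from gatedrnn.network import default_initial_state, rk4_step, _input_accumulator
from gatedrnn.params import ParameterError


class TestMakeNetwork:
    def test_fixed_seed_is_bit_reproducible(self):
        p = NetworkParams(n_units=500, g_h=1.0, seed=1)
        a, b = make_network(p), make_network(p)
        assert np.array_equal(a.J_h, b.J_h)
        assert np.array_equal(a.J_z, b.J_z)
        assert np.array_equal(a.J_r, b.J_r)

    def test_coupling_statistics_at_large_n(self):
        n = 2000
        net = make_network(NetworkParams(n_units=n, g_h=1.0, seed=2))
        for J in (net.J_h, net.J_z, net.J_r):
            assert 0.8 / n < J.var() < 1.2 / n
            assert abs(J.mean()) < 4.0 / n

    def test_matrices_are_mutually_independent_streams(self):
        net = make_network(NetworkParams(n_units=300, g_h=1.0, seed=2))
        assert not np.array_equal(net.J_h, net.J_z)
        corr = np.corrcoef(net.J_h.ravel(), net.J_z.ravel())[0, 1]
        assert abs(corr) < 0.02

    def test_smallest_legal_size(self):
        net = make_network(NetworkParams(n_units=2, g_h=1.0, seed=7))
        assert net.J_h.shape == (2, 2) and np.all(np.isfinite(net.J_h))

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ParameterError):
            NetworkParams(n_units=0, g_h=1.0)


class TestSimulate:
    def test_zero_gain_state_decays_at_gate_rate(self):
        # g_h = 0 silences the recurrent drive; h decays at rate sigma_z = 1/2
        net = make_network(NetworkParams(n_units=50, g_h=0.0, seed=1))
        traj = simulate(net, t_final=40.0)
        assert np.linalg.norm(traj.h[-1]) < 1e-6 * np.linalg.norm(traj.h[0])

    def test_classical_rnn_limit_matches_direct_oracle(self):
        # both gates pinned to 1: h obeys dx/dt = -x + J phi(x) exactly
        p = NetworkParams(n_units=100, g_h=0.5, seed=3)
        net = make_network(p, gate_override={"z": 1.0, "r": 1.0})
        h0, z0, r0 = default_initial_state(net)
        traj = simulate(net, t_final=20.0, initial_state=(h0, z0, r0))

        dt, x = 0.05, h0.copy()
        J = net.J_h

        def f(x):
            return -x + J @ np.tanh(0.5 * x)

        for _ in range(400):
            k1 = f(x)
            k2 = f(x + dt / 2 * k1)
            k3 = f(x + dt / 2 * k2)
            k4 = f(x + dt * k3)
            x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert np.allclose(traj.h[-1], x, atol=1e-8)

    def test_subcritical_classical_limit_converges_to_zero(self):
        net = make_network(NetworkParams(n_units=100, g_h=0.5, seed=3),
                           gate_override={"z": 1.0, "r": 1.0})
        traj = simulate(net, t_final=60.0)
        assert np.linalg.norm(traj.h[-1]) < 1e-4

    def test_chaotic_state_has_stationary_positive_variance(self, chaotic_traj):
        var = np.var(chaotic_traj.h, axis=1)
        assert var[-1] > 0.01
        assert is_stationary(chaotic_traj)

    def test_seed_determinism_of_trajectories(self):
        p = NetworkParams(n_units=60, g_h=2.5, alpha_r=1.0, seed=11)
        a = simulate(make_network(p), t_final=10.0)
        b = simulate(make_network(p), t_final=10.0)
        assert np.array_equal(a.h, b.h) and np.array_equal(a.r, b.r)

    def test_boundedness_under_bounded_input(self, rng):
        # sigma_z >= 0 and bounded phi, sigma_r keep the flow globally bounded
        net = make_network(NetworkParams(n_units=80, g_h=5.0, alpha_r=3.0, seed=4))
        from gatedrnn import InputProtocol
        inp = [InputProtocol("h", rng.uniform(-1, 1, 80), [(0.0, 50.0)])]
        traj = simulate(net, inputs=inp, t_final=50.0,
                        initial_state=(rng.normal(0, 2, 80),) * 3)
        bound = max(np.abs(traj.h[0]).max(),
                    np.abs(net.J_h).sum(axis=1).max() + 1.0)
        assert np.abs(traj.h).max() <= bound + 1e-6

    def test_halving_dt_changes_endpoint_by_under_one_percent(self):
        p = NetworkParams(n_units=80, g_h=1.5, seed=6)  # chaos-free
        net = make_network(p)
        init = default_initial_state(net)
        a = simulate(net, t_final=50.0, dt=0.05, initial_state=init)
        b = simulate(net, t_final=50.0, dt=0.025, initial_state=init)
        na, nb = np.linalg.norm(a.h[-1]), np.linalg.norm(b.h[-1])
        assert abs(na - nb) / max(nb, 1e-12) < 0.01

    def test_invalid_grid_rejected(self, chaotic_net):
        with pytest.raises(ValueError):
            simulate(chaotic_net, t_final=-1.0)
        with pytest.raises(ValueError):
            simulate(chaotic_net, t_final=1.0, dt=0.0)


class TestSteadyStateMoments:
    def _zero_traj(self, g_h=3.0, n=40, steps=200):
        p = NetworkParams(n_units=n, g_h=g_h)
        zeros = np.zeros((steps, n))
        return Trajectory(times=np.arange(steps) * 0.05, h=zeros, z=zeros.copy(),
                          r=zeros.copy(), dt=0.05, params=p)

    def test_values_at_the_origin(self):
        mom = steady_state_moments(self._zero_traj(g_h=3.0), burn_in_fraction=0.0)
        assert mom.phi2 == 0.0
        assert mom.dphi2 == pytest.approx(9.0)
        assert mom.sz_mean == pytest.approx(0.5)
        assert mom.sr2 == pytest.approx(0.25)

    def test_chaotic_variance_matches_mean_field_prediction(self, chaotic_traj):
        # independent oracle: the static mean-field self-consistency
        mom = steady_state_moments(chaotic_traj)
        sol = solve_fixed_point(chaotic_traj.params, "nonzero")
        assert abs(mom.h2 - sol.delta_h) / sol.delta_h < 0.10

    def test_too_short_window_is_an_error(self):
        with pytest.raises(AnalysisError):
            steady_state_moments(self._zero_traj(steps=50), burn_in_fraction=0.99)
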