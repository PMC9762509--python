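import math

import numpy as np
import pytest

from gatedrnn import NetworkParams, make_network, simulate, steady_state_moments
from gatedrnn.mft import moments_at_fixed_point, solve_fixed_point
from gatedrnn.network import StateMoments, _deriv, _input_accumulator
from gatedrnn.spectra import (
    curve_values,
    empirical_spectrum,
    fp_unstable,
    fraction_inside,
    instantaneous_jacobian,
    limiting_density_infinite_alpha_z,
    marginal_stability_radius,
    near_zero_fraction,
    pinching_diagnostic,
    spectral_curve,
)


def _zero_fp_moments(g_h, **kw):
    p = NetworkParams(n_units=2, g_h=g_h, **kw)
    return moments_at_fixed_point(p, solve_fixed_point(p, "zero"))


class TestInstantaneousJacobian:
    def test_blocks_at_the_origin(self):
        p = NetworkParams(n_units=30, g_h=2.0, seed=1)
        net = make_network(p)
        n = 30
        J = instantaneous_jacobian(net, (np.zeros(n),) * 3)
        # hh block: sigma_z(0) (-1 + J_h [phi'(0) sigma_r(0)]) = (1/2)(-1 + J_h g/2)
        expected = 0.5 * (-np.eye(n) + net.J_h * (2.0 * 0.5))
        assert np.allclose(J[:n, :n], expected)
        assert np.allclose(J[:n, n:2 * n], 0.0)  # D vanishes at a fixed point
        assert np.allclose(J[:n, 2 * n:], 0.0)  # phi(0) = 0 silences the r-channel
        assert np.allclose(np.diag(J[n:2 * n, n:2 * n]), -1.0)

    def test_matches_central_difference_of_vector_field(self, small_mixed_net):
        net = small_mixed_net
        n = net.n
        rng = np.random.default_rng(0)
        h, z, r = rng.normal(0, 0.5, (3, n))
        J = instantaneous_jacobian(net, (h, z, r))
        inp = _input_accumulator([], n)

        def F(x):
            dh, dz, dr = _deriv(net, 0.0, x[:n], x[n:2 * n], x[2 * n:], inp)
            return np.concatenate([dh, dz, dr])

        x0 = np.concatenate([h, z, r])
        eps = 1e-6
        for j in range(0, 3 * n, 7):
            e = np.zeros(3 * n)
            e[j] = eps
            col = (F(x0 + e) - F(x0 - e)) / (2 * eps)
            assert np.abs(col - J[:, j]).max() < 1e-5

    def test_pinned_gates_recover_classical_hh_block(self):
        p = NetworkParams(n_units=25, g_h=1.3, seed=2)
        net = make_network(p, gate_override={"z": 1.0, "r": 1.0})
        rng = np.random.default_rng(3)
        h = rng.normal(0, 0.5, 25)
        J = instantaneous_jacobian(net, (h, np.zeros(25), np.zeros(25)))
        dphi = net.dphi(h)
        expected = -np.eye(25) + net.J_h * dphi[None, :]
        assert np.allclose(J[:25, :25], expected)
        # gate rows remain present
        assert np.any(J[25:50, :25] != 0.0)

    def test_dimension_mismatch_rejected(self, small_mixed_net):
        with pytest.raises(ValueError):
            instantaneous_jacobian(small_mixed_net, np.zeros(10))


class TestEmpiricalSpectrum:
    def test_diagonal_matrix(self):
        a = np.array([1.0, -2.0, 0.5])
        assert sorted(empirical_spectrum(np.diag(a)).real) == sorted(a)

    def test_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            empirical_spectrum(np.array([[np.nan, 0], [0, 1.0]]))


class TestSpectralCurve:
    def test_zero_fp_boundary_is_the_closed_form_circle(self):
        # |lambda + 1/2| = g/4, derived by substituting the origin values
        for g in (1.2, 3.0):
            mom = _zero_fp_moments(g)
            theta = np.linspace(0, 2 * np.pi, 64)
            circle = -0.5 + (g / 4) * np.exp(1j * theta)
            assert np.abs(curve_values(mom, circle)).max() < 1e-8

    @pytest.mark.parametrize("g,edge", [(1.2, -0.2), (2.0, 0.0), (3.0, 0.25)])
    def test_leading_edge_of_zero_fp(self, g, edge):
        res = spectral_curve(_zero_fp_moments(g), n_grid=400)
        assert res.leading_edge == pytest.approx(edge, abs=1e-3)

    def test_imag_intercept_of_supercritical_circle(self):
        # circle crosses the imaginary axis at sqrt((g/4)^2 - 1/4)
        res = spectral_curve(_zero_fp_moments(3.0), n_grid=400)
        assert res.imag_intercept == pytest.approx(math.sqrt(0.5625 - 0.25), abs=1e-3)
        assert spectral_curve(_zero_fp_moments(1.5), n_grid=300).imag_intercept == 0.0

    def test_intercept_shrinks_with_update_gate_gain(self):
        # pinching: a more switchlike update gate pulls the curve inward
        intercepts = []
        for az in (0.0, 5.0, 15.0):
            p = NetworkParams(n_units=300, g_h=3.0, alpha_z=az, seed=8)
            traj = simulate(make_network(p), t_final=100.0, record_every=4)
            mom = steady_state_moments(traj)
            intercepts.append(spectral_curve(mom, n_grid=300).imag_intercept)
        assert intercepts[0] > intercepts[1] > intercepts[2]


class TestStabilityCriteria:
    def test_zero_fp_threshold_at_gain_two(self):
        assert not fp_unstable(_zero_fp_moments(1.9))
        assert fp_unstable(_zero_fp_moments(2.1))

    def test_equality_counts_as_stable(self):
        mom = StateMoments(phi2=0.0, dphi2=4.0, sr2=0.25, dsr2=0.0,
                           sz_mean=0.5, sz2=0.25)
        assert not fp_unstable(mom)

    def test_criterion_matches_leading_edge_sign(self):
        rng = np.random.default_rng(7)
        for _ in range(12):
            g = rng.uniform(1.2, 3.2)
            ar = rng.uniform(0.0, 6.0)
            p = NetworkParams(n_units=2, g_h=g, alpha_r=ar)
            branch = "nonzero" if rng.random() < 0.5 else "zero"
            mom = moments_at_fixed_point(p, solve_fixed_point(p, branch))
            res = spectral_curve(mom, n_grid=300)
            edge_positive = res.leading_edge > 1e-4
            if abs(res.leading_edge) > 1e-4:
                assert fp_unstable(mom) == edge_positive


class TestMarginalStability:
    def _binary_moments(self, g, alpha_r=0.0):
        p = NetworkParams(n_units=2, g_h=g, alpha_r=alpha_r, alpha_z=math.inf)
        return moments_at_fixed_point(p, solve_fixed_point(p, "nonzero"))

    def test_radius_collapses_to_sqrt_a_without_output_gate(self):
        mom = StateMoments(phi2=0.3, dphi2=5.0, sr2=0.25, dsr2=0.0,
                           sz_mean=0.5, sz2=0.5, binary_z=True)
        a = 5.0 * 0.5 * 0.25
        assert marginal_stability_radius(mom) == pytest.approx(math.sqrt(a))

    def test_radius_increasing_and_below_one_inside_window(self):
        rhos = [marginal_stability_radius(self._binary_moments(g))
                for g in (2.5, 3.5, 4.5, 5.5)]
        assert all(b > a for a, b in zip(rhos, rhos[1:]))
        assert all(r < 1.0 for r in rhos)

    def test_radius_exceeds_one_beyond_window(self):
        assert marginal_stability_radius(self._binary_moments(7.0)) > 1.0


class TestLimitingDensity:
    def test_pure_disk_when_all_gates_open_and_unsaturated(self):
        d = limiting_density_infinite_alpha_z(1.0, 1.0, 3.0)
        assert d["weight_at_zero"] == 0.0
        assert d["weight_at_minus_one"] == 0.0
        assert d["disk_weight"] == 1.0

    def test_all_mass_at_zero_when_gates_closed(self):
        d = limiting_density_infinite_alpha_z(0.0, 0.7, 3.0)
        assert d["weight_at_zero"] == 1.0 and d["disk_weight"] == 0.0

    def test_weights_sum_to_one(self):
        d = limiting_density_infinite_alpha_z(0.4, 0.6, 2.0)
        total = d["weight_at_zero"] + d["weight_at_minus_one"] + d["disk_weight"]
        assert total == pytest.approx(1.0)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            limiting_density_infinite_alpha_z(1.2, 0.5, 2.0)

    def test_zero_mode_count_matches_switchlike_surrogate(self):
        # half the update gates are closed at beta_z = 0, freezing ~N/2 modes
        p = NetworkParams(n_units=300, g_h=3.0, alpha_z=100.0, seed=4)
        net = make_network(p)
        traj = simulate(net, t_final=120.0, record_every=4)
        mom = steady_state_moments(traj)
        eigs = empirical_spectrum(instantaneous_jacobian(net, traj.final_state()))
        frac = near_zero_fraction(eigs, 0.05, n_units=300)
        assert abs(frac - (1.0 - mom.sz_mean)) < 0.05


class TestPinching:
    def test_leading_edge_and_cluster_inside_marginal_window(self):
        # g_h = 3 supports pinching: switchlike update gate pins the edge at 0
        p = NetworkParams(n_units=250, g_h=3.0, seed=9)
        tab = pinching_diagnostic(p, [1.0, 5.0, 15.0, 30.0], t_relax=80.0)
        edges = tab["leading_edge"].to_numpy()
        assert edges[-1] < edges[0]
        nz = tab["near_zero_fraction"].to_numpy()
        assert nz[-1] > nz[0]
        assert np.isfinite(tab.attrs["erf_fit"]["rms_residual"])

    def test_no_pinching_at_large_gain(self):
        # outside the marginal window the zero modes are buried in the bulk
        p = NetworkParams(n_units=250, g_h=8.0, seed=9)
        tab = pinching_diagnostic(p, [5.0, 30.0], t_relax=80.0)
        icpt = tab["imag_intercept"].to_numpy()
        assert icpt[-1] > 0.25  # does not shrink toward zero


class TestFractionInside:
    def test_chaotic_state_spectrum_lies_in_predicted_support(self, chaotic_net,
                                                              chaotic_traj):
        mom = steady_state_moments(chaotic_traj)
        eigs = empirical_spectrum(
            instantaneous_jacobian(chaotic_net, chaotic_traj.final_state()))
        assert fraction_inside(mom, eigs) >= 0.95
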