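"""Lyapunov spectra, attractor dimension, and the mean-field lambda_max.

The Lyapunov spectrum is computed with the standard Benettin/QR method: a
set of tangent vectors is co-integrated with the trajectory under the
instantaneous Jacobian (same fixed-step RK4 grid, with stage-matched
linearization) and reorthonormalized at a fixed interval; the exponents are
the time averages of the log diagonal of R.

The dynamical mean-field prediction for the maximal exponent is the largest
eigenvalue ``kappa`` of a generalized (quadratic-in-kappa) eigenproblem on
the two-time correlation functions of the steady state,

    [(<sigma_z> + kappa)^2 - d^2/dtau^2] chi_h
        = <sigma_z^2> [ C_phi'(tau) C_sigr(tau) chi_h
                        + C_phi(tau) C_sigr'(tau) chi_r ],
    [(1 + tau_r kappa)^2 - tau_r^2 d^2/dtau^2] chi_r = C_phi'(tau) chi_h,

valid when the update-gate gain is zero, where the h-field is Gaussian and
Price's theorem converts variational derivatives of correlators into plain
correlation functions (site-wise h and r are independent because the
coupling matrices are independent, so the product-field derivative
factorizes; the h-r cross-susceptibility is dropped, consistent with that
independence).  For a sensitive update gate the h-distribution is strongly
non-Gaussian and the closure is refused rather than extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import (
    AnalysisError,
    GatedNetwork,
    InputProtocol,
    Trajectory,
    _deriv,
    _input_accumulator,
    default_initial_state,
    is_stationary,
    substream,
)
from .params import NetworkParams, gate_value

__all__ = [
    "LyapunovResult",
    "CorrelatorSet",
    "lyapunov_spectrum",
    "max_lyapunov",
    "kaplan_yorke",
    "measure_correlators",
    "dmft_lambda_max",
    "UnsupportedRegimeError",
]


class UnsupportedRegimeError(ValueError):
    """The mean-field closure is not valid for the requested parameters."""


@dataclass
class LyapunovResult:
    exponents: np.ndarray  # nonincreasing, per unit time
    k: int
    t_total: float
    t_transient: float
    reorth_interval: float
    ky_dimension: float

    @property
    def lambda_max(self) -> float:
        return float(self.exponents[0])


def _tangent_deriv(net: GatedNetwork, h, z, r, Vh, Vz, Vr):
    """Jacobian-vector products at a state, in block form (no dense matrix)."""
    p = net.params
    phi, dphi = net.phi(h), net.dphi(h)
    sr, dsr = net.sigma_r(r), net.dsigma_r(r)
    sz, dsz = net.sigma_z(z), net.dsigma_z(z)
    drive = net.J_h @ (phi * sr)
    D = dsz * (-h + drive)
    dVh = sz[:, None] * (-Vh + net.J_h @ ((dphi * sr)[:, None] * Vh)
                         + net.J_h @ ((phi * dsr)[:, None] * Vr)) + D[:, None] * Vz
    dVz = (net.J_z @ (dphi[:, None] * Vh) - Vz) / p.tau_z
    dVr = (net.J_r @ (dphi[:, None] * Vh) - Vr) / p.tau_r
    return dVh, dVz, dVr


def _joint_rk4_step(net, t, h, z, r, V, dt, inp):
    """RK4 step of state and tangent block (3N x k) together.

    The tangent stage derivatives use the Jacobian evaluated at the
    corresponding Runge-Kutta stage states of the nonlinear flow.
    """
    n = net.n
    Vh, Vz, Vr = V[:n], V[n:2 * n], V[2 * n:]

    k1s = _deriv(net, t, h, z, r, inp)
    k1v = _tangent_deriv(net, h, z, r, Vh, Vz, Vr)

    a = (h + dt / 2 * k1s[0], z + dt / 2 * k1s[1], r + dt / 2 * k1s[2])
    k2s = _deriv(net, t + dt / 2, *a, inp)
    k2v = _tangent_deriv(net, *a, Vh + dt / 2 * k1v[0], Vz + dt / 2 * k1v[1], Vr + dt / 2 * k1v[2])

    b = (h + dt / 2 * k2s[0], z + dt / 2 * k2s[1], r + dt / 2 * k2s[2])
    k3s = _deriv(net, t + dt / 2, *b, inp)
    k3v = _tangent_deriv(net, *b, Vh + dt / 2 * k2v[0], Vz + dt / 2 * k2v[1], Vr + dt / 2 * k2v[2])

    c = (h + dt * k3s[0], z + dt * k3s[1], r + dt * k3s[2])
    k4s = _deriv(net, t + dt, *c, inp)
    k4v = _tangent_deriv(net, *c, Vh + dt * k3v[0], Vz + dt * k3v[1], Vr + dt * k3v[2])

    h2 = h + dt / 6 * (k1s[0] + 2 * k2s[0] + 2 * k3s[0] + k4s[0])
    z2 = z + dt / 6 * (k1s[1] + 2 * k2s[1] + 2 * k3s[1] + k4s[1])
    r2 = r + dt / 6 * (k1s[2] + 2 * k2s[2] + 2 * k3s[2] + k4s[2])
    V2 = np.empty_like(V)
    V2[:n] = Vh + dt / 6 * (k1v[0] + 2 * k2v[0] + 2 * k3v[0] + k4v[0])
    V2[n:2 * n] = Vz + dt / 6 * (k1v[1] + 2 * k2v[1] + 2 * k3v[1] + k4v[1])
    V2[2 * n:] = Vr + dt / 6 * (k1v[2] + 2 * k2v[2] + 2 * k3v[2] + k4v[2])
    return h2, z2, r2, V2


def lyapunov_spectrum(net: GatedNetwork, k: int = 50, t_total: float = 2000.0,
                      t_transient: float = 200.0, reorth_interval: float = 1.0,
                      dt: float = 0.05, inputs: Sequence[InputProtocol] = (),
                      initial_state=None, seed: Optional[int] = None,
                      warmup_blocks: int = 10) -> LyapunovResult:
    """First ``k`` Lyapunov exponents by Benettin QR reorthonormalization.

    ``t_transient`` of free relaxation is discarded before tangent
    accumulation starts, and the tangent basis is additionally evolved for
    ``warmup_blocks`` reorthonormalization intervals without accumulating,
    so the random basis first aligns with the Oseledets subspaces;
    exponents are per unit time (the h time constant).
    """
    n3 = 3 * net.n
    if not 1 <= k <= n3:
        raise ValueError(f"need 1 <= k <= 3N, got k={k}")
    if t_total <= t_transient:
        raise ValueError("t_total must exceed t_transient")
    from .network import rk4_step

    inp = _input_accumulator(inputs, net.n)
    if initial_state is None:
        h, z, r = default_initial_state(net, seed=seed)
    else:
        h, z, r = (np.array(x, dtype=float, copy=True) for x in initial_state)

    n_trans = int(round(t_transient / dt))
    for step in range(n_trans):
        h, z, r = rk4_step(net, step * dt, h, z, r, dt, inp)
    t0 = n_trans * dt

    rng = substream(net.params.seed if seed is None else seed, "init", index=7)
    V, _ = np.linalg.qr(rng.normal(size=(n3, k)))

    m = max(1, int(round(reorth_interval / dt)))
    n_steps = int(round((t_total - t_transient) / dt))
    n_blocks = n_steps // m
    if n_blocks < 1:
        raise ValueError("accumulation window shorter than one reorthonormalization")

    log_sums = np.zeros(k)
    n_accum = 0
    for blk in range(-warmup_blocks, n_blocks):
        for s in range(m):
            t = t0 + (blk + warmup_blocks) * m * dt + s * dt
            h, z, r, V = _joint_rk4_step(net, t, h, z, r, V, dt, inp)
        Q, R = np.linalg.qr(V)
        diag = np.diag(R)
        if np.any(np.abs(diag) < 1e-300):
            raise FloatingPointError("rank loss in QR reorthonormalization")
        sign = np.sign(diag)
        if blk >= 0:
            log_sums += np.log(np.abs(diag))
            n_accum += 1
        V = Q * sign[None, :]

    exps = np.sort(log_sums / (n_accum * m * dt))[::-1]
    try:
        ky = kaplan_yorke(exps)
    except ValueError:
        ky = math.nan
    return LyapunovResult(exponents=exps, k=k, t_total=t_total,
                         t_transient=t_transient, reorth_interval=reorth_interval,
                         ky_dimension=ky)


def max_lyapunov(net: GatedNetwork, t_total: float = 300.0, t_transient: float = 50.0,
                 dt: float = 0.05, inputs: Sequence[InputProtocol] = (),
                 initial_state=None, seed: Optional[int] = None) -> float:
    """Maximal Lyapunov exponent (single tangent vector)."""
    res = lyapunov_spectrum(net, k=1, t_total=t_total, t_transient=t_transient,
                            reorth_interval=1.0, dt=dt, inputs=inputs,
                            initial_state=initial_state, seed=seed)
    return res.lambda_max


def kaplan_yorke(exponents) -> float:
    """Kaplan-Yorke upper bound on the attractor dimension.

    ``D_A = M + (sum_{i<=M} lambda_i) / |lambda_{M+1}|`` with ``M`` the
    largest index whose partial sum is still nonnegative.  Returns 0 when
    even the largest exponent is negative (point attractor).
    """
    lam = np.asarray(exponents, dtype=float)
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("exponents must be sorted nonincreasing")
    if lam[0] < 0:
        return 0.0
    csum = np.cumsum(lam)
    nonneg = np.nonzero(csum >= 0)[0]
    M = int(nonneg[-1]) + 1  # 1-based count
    if M >= len(lam):
        raise ValueError(
            "all partial sums nonnegative; compute more exponents to locate M+1")
    return float(M + csum[M - 1] / abs(lam[M]))


@dataclass
class CorrelatorSet:
    """Two-time correlation functions measured in a stationary state.

    ``lags`` is the one-sided lag grid (the correlators are even in tau);
    ``C`` maps field names (``h``, ``phi``, ``dphi``, ``sz``, ``dsz``,
    ``sr``, ``dsr``, ``phisr``) to arrays over the lags.
    """

    lags: np.ndarray
    C: dict
    window: float
    params: NetworkParams
    stationary: bool = True

    def symmetric(self, name: str):
        """(tau, C(tau)) on the symmetric grid [-max_lag, max_lag]."""
        c = self.C[name]
        tau = np.concatenate([-self.lags[:0:-1], self.lags])
        return tau, np.concatenate([c[:0:-1], c])


def _autocorr_columns(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Population-averaged time autocorrelation via FFT; x is (T, N)."""
    t_len = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * t_len)))
    X = np.fft.rfft(x, n=nfft, axis=0)
    full = np.fft.irfft(np.abs(X) ** 2, n=nfft, axis=0)[:n_lags]
    counts = (t_len - np.arange(n_lags)).astype(float)
    return full.mean(axis=1) / counts


def measure_correlators(traj: Trajectory, max_lag: float = 20.0,
                        burn_in: float = 0.5) -> CorrelatorSet:
    """Estimate the stationary two-time correlators from a trajectory.

    Averages over units and over time origins in the post-burn-in window
    (which must be at least ``10 * max_lag`` long).  A failed stationarity
    check flags the result instead of raising.
    """
    p = traj.params
    start = int(math.ceil(burn_in * traj.n_samples))
    dt_lag = traj.dt * traj.record_every
    window = (traj.n_samples - start - 1) * dt_lag
    if window < 10 * max_lag:
        raise AnalysisError(
            f"post-burn-in window {window:g} shorter than 10*max_lag = {10 * max_lag:g}")
    n_lags = int(round(max_lag / dt_lag)) + 1

    from .params import activation, activation_deriv, gate_deriv

    h = traj.h[start:]
    r = traj.r[start:]
    z = traj.z[start:]
    fields = {
        "h": h,
        "phi": activation(h, p.g_h, p.beta_h),
        "dphi": activation_deriv(h, p.g_h, p.beta_h),
        "sz": gate_value(z, p.alpha_z, p.beta_z),
        "dsz": gate_deriv(z, p.alpha_z, p.beta_z),
        "sr": gate_value(r, p.alpha_r, p.beta_r),
        "dsr": gate_deriv(r, p.alpha_r, p.beta_r),
    }
    fields["phisr"] = fields["phi"] * fields["sr"]
    C = {k: _autocorr_columns(v, n_lags) for k, v in fields.items()}
    try:
        stat = is_stationary(traj)
    except AnalysisError:
        stat = False
    return CorrelatorSet(lags=np.arange(n_lags) * dt_lag, C=C, window=window,
                         params=p, stationary=stat)


def dmft_lambda_max(correlators: CorrelatorSet, params: Optional[NetworkParams] = None) -> float:
    """Mean-field maximal Lyapunov exponent from measured correlators.

    Solves the quadratic-in-kappa eigenproblem (module docstring) on the
    symmetric lag grid with Dirichlet boundary conditions (the
    susceptibilities decay within the lag window in the supported regimes),
    via companion linearization of the quadratic pencil.  Only valid for
    ``alpha_z = 0``; other values raise :class:`UnsupportedRegimeError`.
    """
    p = params if params is not None else correlators.params
    if p.alpha_z != 0.0:
        raise UnsupportedRegimeError(
            "the Gaussian/Price closure for lambda_max requires alpha_z = 0 "
            "(for a sensitive update gate the h-field is strongly non-Gaussian)")

    s0 = float(np.asarray(gate_value(np.array([0.0]), 0.0, p.beta_z))[0])
    tau, c_dphi = correlators.symmetric("dphi")
    _, c_phi = correlators.symmetric("phi")
    _, c_sr = correlators.symmetric("sr")
    _, c_dsr = correlators.symmetric("dsr")
    n = len(tau)
    d = tau[1] - tau[0]

    # second difference with chi = 0 outside the window
    main = np.full(n, -2.0 / d ** 2)
    off = np.full(n - 1, 1.0 / d ** 2)
    D2 = np.diag(main) + np.diag(off, 1) + np.diag(off, -1)

    I = np.eye(n)
    # quadratic pencil  kappa^2 M2 + kappa M1 + M0  on (chi_h, chi_r)
    M2 = np.block([[I, np.zeros((n, n))],
                   [np.zeros((n, n)), p.tau_r ** 2 * I]])
    M1 = np.block([[2 * s0 * I, np.zeros((n, n))],
                   [np.zeros((n, n)), 2 * p.tau_r * I]])
    A = s0 ** 2 * I - D2 - s0 ** 2 * np.diag(c_dphi * c_sr)
    B = -s0 ** 2 * np.diag(c_phi * c_dsr)
    Cc = -np.diag(c_dphi)
    Dd = I - p.tau_r ** 2 * D2
    M0 = np.block([[A, B], [Cc, Dd]])

    # companion linearization: eigenvalues kappa of the pencil
    m = 2 * n
    comp = np.zeros((2 * m, 2 * m))
    comp[:m, m:] = np.eye(m)
    comp[m:, :m] = -np.linalg.solve(M2, M0)
    comp[m:, m:] = -np.linalg.solve(M2, M1)
    ev = np.linalg.eigvals(comp)
    real = ev[np.abs(ev.imag) < 1e-6].real
    if len(real) == 0:
        real = ev.real
    return float(np.max(real))
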