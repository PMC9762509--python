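"""Network construction and integration of the gated RNN dynamics.

The model is a continuous-time recurrent network of ``N`` units with two
multiplicative gates,

    dh_i/dt = sigma_z(z_i) [ -h_i + R_i ] + I^h_i(t),
    tau_x dx_i/dt = -x_i + sum_j J^x_ij phi(h_j) + I^x_i(t),   x in {z, r},

with recurrent drive ``R_i = sum_j J^h_ij phi(h_j) sigma_r(r_j)`` and
``phi(x) = tanh(g_h x + beta_h)``.  The three coupling matrices are
independent Gaussian matrices with entries of variance ``1/N``.  The update
gate ``sigma_z`` acts as an adaptive per-unit time constant, the output gate
``sigma_r`` modulates each unit's recurrent output.  Pinning both gates to 1
recovers the classical additive RNN ``dx/dt = -x + J phi(x)``.

Integration is fixed-step RK4: the tangent-space (Lyapunov) machinery needs
a fixed step, and the vector field is smooth for finite gate gains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .params import (
    NetworkParams,
    activation,
    activation_deriv,
    gate_deriv,
    gate_value,
)

__all__ = [
    "GatedNetwork",
    "InputProtocol",
    "Trajectory",
    "StateMoments",
    "make_network",
    "simulate",
    "steady_state_moments",
    "is_stationary",
    "IntegrationError",
    "AnalysisError",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator encounters a non-finite state."""


class AnalysisError(ValueError):
    """Raised when a trajectory is unsuitable for the requested analysis."""


# fixed substream layout for the root seed; new consumers append, never reorder
_STREAMS = {"J_h": 0, "J_z": 1, "J_r": 2, "init": 3, "input": 4, "trials": 5}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named, reproducible random substream derived from a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name], index))
    )


@dataclass
class GatedNetwork:
    """A realized gated RNN: parameters plus sampled coupling matrices.

    ``gate_override`` optionally pins a gate to a constant (e.g.
    ``{"z": 1.0, "r": 1.0}`` recovers the classical RNN); a pinned gate has
    zero derivative in the linearized dynamics.
    """

    params: NetworkParams
    J_h: np.ndarray
    J_z: np.ndarray
    J_r: np.ndarray
    gate_override: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.params.n_units

    # --- pointwise nonlinearities, honoring overrides -------------------
    def phi(self, h):
        return activation(h, self.params.g_h, self.params.beta_h)

    def dphi(self, h):
        return activation_deriv(h, self.params.g_h, self.params.beta_h)

    def sigma_z(self, z):
        if "z" in self.gate_override:
            return np.full_like(np.asarray(z, dtype=float), self.gate_override["z"])
        return gate_value(z, self.params.alpha_z, self.params.beta_z)

    def dsigma_z(self, z):
        if "z" in self.gate_override:
            return np.zeros_like(np.asarray(z, dtype=float))
        return gate_deriv(z, self.params.alpha_z, self.params.beta_z)

    def sigma_r(self, r):
        if "r" in self.gate_override:
            return np.full_like(np.asarray(r, dtype=float), self.gate_override["r"])
        return gate_value(r, self.params.alpha_r, self.params.beta_r)

    def dsigma_r(self, r):
        if "r" in self.gate_override:
            return np.zeros_like(np.asarray(r, dtype=float))
        return gate_deriv(r, self.params.alpha_r, self.params.beta_r)


def make_network(params: NetworkParams, gate_override: Optional[dict] = None) -> GatedNetwork:
    """Draw the three coupling matrices ``J^h, J^z, J^r ~ N(0, 1/N)``.

    Bit-for-bit reproducible for a fixed ``params.seed``: each matrix comes
    from its own named substream of the root seed.
    """
    n = params.n_units
    scale = 1.0 / math.sqrt(n)
    mats = {}
    for name in ("J_h", "J_z", "J_r"):
        rng = substream(params.seed, name)
        mats[name] = rng.normal(0.0, scale, size=(n, n))
    return GatedNetwork(params=params, gate_override=dict(gate_override or {}), **mats)


@dataclass
class InputProtocol:
    """A static input vector gated on and off over time windows.

    ``target`` selects which equation receives the input (``h``, ``z`` or
    ``r``); ``schedule`` is a list of ``(t_on, t_off)`` windows during which
    ``vector`` is added to the corresponding right-hand side.
    """

    target: str
    vector: np.ndarray
    schedule: Sequence[tuple] = ((0.0, math.inf),)
    tag: str = "custom"

    def __post_init__(self):
        if self.target not in ("h", "z", "r"):
            raise ValueError(f"target must be one of h/z/r, got {self.target!r}")
        self.vector = np.asarray(self.vector, dtype=float)
        for t_on, t_off in self.schedule:
            if not t_on < t_off:
                raise ValueError(f"need t_on < t_off, got ({t_on}, {t_off})")

    def active(self, t: float) -> bool:
        return any(t_on <= t < t_off for t_on, t_off in self.schedule)

    @staticmethod
    def gaussian_static(target: str, n: int, sigma: float, rng: np.random.Generator,
                        schedule=((0.0, math.inf),)) -> "InputProtocol":
        """Frozen i.i.d. ``N(0, sigma^2)`` input vector."""
        return InputProtocol(target, rng.normal(0.0, sigma, n), schedule,
                             tag=f"gaussian_static({sigma})")

    def describe(self) -> dict:
        return {
            "target": self.target,
            "tag": self.tag,
            "schedule": [[float(a), float(b)] for a, b in self.schedule],
            "vector_norm": float(np.linalg.norm(self.vector)),
        }


@dataclass
class Trajectory:
    """Time grid plus recorded state history of a simulation run."""

    times: np.ndarray
    h: np.ndarray  # (timesteps, N)
    z: np.ndarray
    r: np.ndarray
    dt: float
    params: NetworkParams
    inputs: tuple = ()
    record_every: int = 1

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def final_state(self):
        return self.h[-1].copy(), self.z[-1].copy(), self.r[-1].copy()


def _input_accumulator(inputs: Sequence[InputProtocol], n: int):
    """Return f(t) -> (I_h, I_z, I_r) with zero-cost fast path."""
    by_target = {"h": [], "z": [], "r": []}
    for p in inputs:
        if len(p.vector) != n:
            raise ValueError("input vector length must equal N")
        by_target[p.target].append(p)
    zero = np.zeros(n)

    def at(t: float):
        out = []
        for tgt in ("h", "z", "r"):
            acc = None
            for p in by_target[tgt]:
                if p.active(t):
                    acc = p.vector if acc is None else acc + p.vector
            out.append(zero if acc is None else acc)
        return out

    return at


def _deriv(net: GatedNetwork, t: float, h, z, r, inp):
    """Right-hand side of the gated RNN ODEs."""
    I_h, I_z, I_r = inp(t)
    phi = net.phi(h)
    drive = net.J_h @ (phi * net.sigma_r(r))
    dh = net.sigma_z(z) * (-h + drive) + I_h
    dz = (-z + net.J_z @ phi + I_z) / net.params.tau_z
    dr = (-r + net.J_r @ phi + I_r) / net.params.tau_r
    return dh, dz, dr


def rk4_step(net: GatedNetwork, t: float, h, z, r, dt: float, inp):
    """One classical RK4 step; returns the new state."""
    k1 = _deriv(net, t, h, z, r, inp)
    k2 = _deriv(net, t + dt / 2, h + dt / 2 * k1[0], z + dt / 2 * k1[1], r + dt / 2 * k1[2], inp)
    k3 = _deriv(net, t + dt / 2, h + dt / 2 * k2[0], z + dt / 2 * k2[1], r + dt / 2 * k2[2], inp)
    k4 = _deriv(net, t + dt, h + dt * k3[0], z + dt * k3[1], r + dt * k3[2], inp)
    h2 = h + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    z2 = z + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    r2 = r + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    return h2, z2, r2


def default_initial_state(net: GatedNetwork, scale: float = 0.1,
                          seed: Optional[int] = None, index: int = 0):
    """i.i.d. ``N(0, scale^2)`` initial state from the ``init`` substream.

    A small random initial condition avoids starting exactly on the
    measure-zero zero fixed point while staying inside its basin when it is
    stable.
    """
    rng = substream(net.params.seed if seed is None else seed, "init", index)
    n = net.n
    return tuple(rng.normal(0.0, scale, n) for _ in range(3))


def simulate(net: GatedNetwork, inputs: Sequence[InputProtocol] = (),
             t_final: float = 100.0, dt: float = 0.05,
             initial_state=None, init_scale: float = 0.1,
             record_every: int = 1, seed: Optional[int] = None) -> Trajectory:
    """Integrate the full 3N-dimensional gated RNN with fixed-step RK4.

    Parameters
    ----------
    inputs:
        Input protocols added to the right-hand sides during their windows.
    initial_state:
        Tuple ``(h0, z0, r0)``; defaults to i.i.d. ``N(0, 0.1^2)`` drawn
        from the network seed's ``init`` substream (override with ``seed``).
    record_every:
        Store every ``record_every``-th step (the first and last steps are
        always stored).

    Raises
    ------
    IntegrationError
        If a non-finite state is encountered; the message names the first
        bad time.  The model itself is globally bounded (``sigma_z >= 0``
        and ``phi``, ``sigma_r`` are bounded), so divergence signals an
        integrator failure, e.g. a too-large ``dt``.
    """
    if dt <= 0 or t_final <= 0:
        raise ValueError("dt and t_final must be positive")
    n = net.n
    if initial_state is None:
        h, z, r = default_initial_state(net, init_scale, seed)
    else:
        h, z, r = (np.array(x, dtype=float, copy=True) for x in initial_state)
        if len(h) != n:
            raise ValueError("initial state length must equal N")
    inp = _input_accumulator(inputs, n)

    n_steps = int(round(t_final / dt))
    rec_idx = list(range(0, n_steps + 1, record_every))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    rec_set = set(rec_idx)

    times = np.empty(len(rec_idx))
    H = np.empty((len(rec_idx), n))
    Z = np.empty((len(rec_idx), n))
    R = np.empty((len(rec_idx), n))
    j = 0
    for step in range(n_steps + 1):
        t = step * dt
        if step in rec_set:
            if not (np.isfinite(h).all() and np.isfinite(z).all() and np.isfinite(r).all()):
                raise IntegrationError(f"non-finite state at t={t:g}")
            times[j] = t
            H[j], Z[j], R[j] = h, z, r
            j += 1
        if step < n_steps:
            h, z, r = rk4_step(net, t, h, z, r, dt, inp)

    return Trajectory(times=times, h=H, z=Z, r=R, dt=dt, params=net.params,
                      inputs=tuple(p.describe() for p in inputs),
                      record_every=record_every)


@dataclass
class StateMoments:
    """Population/time averages of the state functions entering the theory.

    These are the order parameters through which the mean-field and
    random-matrix results are expressed: ``phi2 = <phi^2>``,
    ``dphi2 = <phi'^2>``, ``sr2 = <sigma_r^2>``, ``dsr2 = <sigma_r'^2>``,
    ``sz_mean = <sigma_z>``, ``sz2 = <sigma_z^2>`` plus raw second moments
    of the state.  The update-gate field enters the spectral curve through a
    lambda-dependent average, so the z-field description is carried along:
    either explicit samples, a Gaussian ``N(z_mean, z_var)``, or a binary
    gate with open fraction ``sz_mean``.
    """

    phi2: float
    dphi2: float
    sr2: float
    dsr2: float
    sz_mean: float
    sz2: float
    h2: float = 0.0
    z2: float = 0.0
    r2: float = 0.0
    alpha_z: float = 0.0
    beta_z: float = 0.0
    tau_z: float = 1.0
    tau_r: float = 1.0
    binary_z: bool = False
    z_mean: float = 0.0
    z_var: float = 0.0
    z_samples: Optional[np.ndarray] = None
    at_fixed_point: bool = False


def steady_state_moments(traj: Trajectory, burn_in_fraction: float = 0.5,
                         max_z_samples: int = 20000) -> StateMoments:
    """Time-and-population averages over the post-burn-in window.

    For large N these empirical averages concentrate on the corresponding
    steady-state mean-field expectations, which is how simulation results
    are fed into the spectral-curve and stability formulas.
    """
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    start = int(math.ceil(burn_in_fraction * traj.n_samples))
    kept = traj.n_samples - start
    if kept < 100:
        raise AnalysisError(
            f"only {kept} samples remain after burn-in; need at least 100")
    p = traj.params
    h, z, r = traj.h[start:], traj.z[start:], traj.r[start:]
    phi = activation(h, p.g_h, p.beta_h)
    dphi = activation_deriv(h, p.g_h, p.beta_h)
    sr = gate_value(r, p.alpha_r, p.beta_r)
    dsr = gate_deriv(r, p.alpha_r, p.beta_r)
    sz = gate_value(z, p.alpha_z, p.beta_z)

    zs = z.ravel()
    if len(zs) > max_z_samples:
        stride = len(zs) // max_z_samples
        zs = zs[::stride]
    return StateMoments(
        phi2=float(np.mean(phi ** 2)),
        dphi2=float(np.mean(dphi ** 2)),
        sr2=float(np.mean(sr ** 2)),
        dsr2=float(np.mean(dsr ** 2)),
        sz_mean=float(np.mean(sz)),
        sz2=float(np.mean(sz ** 2)),
        h2=float(np.mean(h ** 2)),
        z2=float(np.mean(z ** 2)),
        r2=float(np.mean(r ** 2)),
        alpha_z=p.alpha_z,
        beta_z=p.beta_z,
        tau_z=p.tau_z,
        tau_r=p.tau_r,
        binary_z=math.isinf(p.alpha_z),
        z_mean=float(np.mean(z)),
        z_var=float(np.var(z)),
        z_samples=zs.copy(),
    )


def population_variance(traj: Trajectory) -> np.ndarray:
    """Across-unit variance of ``h`` at each recorded time."""
    return np.var(traj.h, axis=1)


def is_stationary(traj: Trajectory, rel_tol: float = 0.2) -> bool:
    """Crude stationarity check used to classify chaotic steady states.

    Compares the mean population variance of ``h`` over the third and
    fourth quarters of the run; relative difference below ``rel_tol``
    counts as stationary.
    """
    v = population_variance(traj)
    q = len(v) // 4
    if q < 5:
        raise AnalysisError("trajectory too short for stationarity check")
    a, b = float(np.mean(v[2 * q:3 * q])), float(np.mean(v[3 * q:]))
    denom = max(abs(a), abs(b), 1e-300)
    return abs(a - b) / denom < rel_tol
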