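"""Static mean-field theory for fixed points of the gated RNN.

At a fixed point every unit satisfies ``h_i = sum_j J^h_ij phi(h_j)
sigma_r(r_j)`` (from the h-equation with ``dh/dt = 0`` and
``sigma_z > 0``), while the gate drives are ``x_i = sum_j J^x_ij phi(h_j)``
for ``x in {z, r}``.  Because the three coupling matrices are independent,
the site variables ``(h_i, z_i, r_i)`` become independent zero-mean
Gaussians in the large-N limit, with variances determined
self-consistently:

    Delta_z = Delta_r = <phi^2>_{Delta_h},
    Delta_h = <phi^2>_{Delta_h} * <sigma_r^2>_{Delta_r} + Delta_in,

where ``Delta_in`` is an optional quenched-input contribution (zero for the
autonomous network; see :func:`phases.biased_critical_line` for its use).
All Gaussian averages are Gauss-Hermite quadratures.

The zero solution (all variances 0) always exists when ``beta_h = 0``; a
nonzero solution appears through a saddle-node of the scalar map
``Delta -> F(Delta)``, which is the fixed-point proliferation transition of
the output gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from numpy.polynomial.hermite_e import hermegauss

from .network import StateMoments
from .params import NetworkParams, activation, activation_deriv, gate_deriv, gate_value

__all__ = [
    "MFTSolution",
    "gaussian_average",
    "solve_fixed_point",
    "nonzero_branch_exists",
    "alpha_r_fp_star",
    "moments_at_fixed_point",
    "fixed_point_table",
]

_N_NODES = 101
_nodes, _weights = hermegauss(_N_NODES)
_weights = _weights / _weights.sum()


def gaussian_average(f: Callable, variance: float, mean: float = 0.0) -> float:
    """``E[f(x)]`` for ``x ~ N(mean, variance)`` by Gauss-Hermite quadrature.

    ``variance = 0`` returns ``f(mean)`` exactly.  101 nodes are ample for
    the bounded sigmoid/tanh integrands used here (convergence was checked
    by doubling the node count).
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    if variance == 0:
        val = float(np.asarray(f(np.array([mean])))[0])
        if not math.isfinite(val):
            raise FloatingPointError("non-finite integrand at the mean")
        return val
    vals = np.asarray(f(mean + math.sqrt(variance) * _nodes), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError("non-finite integrand at a quadrature node")
    return float(_weights @ vals)


@dataclass
class MFTSolution:
    """Self-consistent Gaussian fixed-point variances."""

    delta_h: float
    delta_z: float
    delta_r: float
    converged: bool
    residual: float
    branch: str  # "zero" | "nonzero"


def _delta_map(params: NetworkParams, delta_h: float, delta_in: float = 0.0) -> float:
    """One application of the self-consistency map F(Delta_h)."""
    p = params
    phi2 = gaussian_average(lambda h: activation(h, p.g_h, p.beta_h) ** 2, delta_h)
    sr2 = gaussian_average(lambda r: gate_value(r, p.alpha_r, p.beta_r) ** 2, phi2)
    return phi2 * sr2 + delta_in


def solve_fixed_point(params: NetworkParams, init_branch: str = "nonzero",
                      init_delta: Optional[float] = None, delta_in: float = 0.0,
                      damping: float = 0.5, tol: float = 1e-10,
                      max_iter: int = 10000) -> MFTSolution:
    """Solve the static mean-field self-consistency for ``Delta_{h,z,r}``.

    ``init_branch="zero"`` returns the trivial solution (exact whenever
    ``beta_h = 0`` and there is no input, since ``phi(0) = 0``).  The
    nonzero branch is found by damped fixed-point iteration seeded at
    ``Delta_h = 1``; the converged answer is classified as "nonzero" when
    ``Delta_h > 1e-6``, which separates the collapsing branch from genuine
    solutions.
    """
    p = params
    if init_branch == "zero":
        if p.beta_h == 0.0 and delta_in == 0.0:
            return MFTSolution(0.0, 0.0, 0.0, True, 0.0, "zero")
        # with a bias/input the "zero" branch is seeded at the input floor
        init_delta = delta_in

    delta = 1.0 if init_delta is None else float(init_delta)
    converged = False
    for _ in range(max_iter):
        new = _delta_map(p, delta, delta_in)
        resid = abs(new - delta)
        if resid < tol:
            delta = new
            converged = True
            break
        delta = (1.0 - damping) * delta + damping * new
    residual = abs(_delta_map(p, delta, delta_in) - delta)
    phi2 = gaussian_average(lambda h: activation(h, p.g_h, p.beta_h) ** 2, delta)
    branch = "nonzero" if delta > 1e-6 else "zero"
    return MFTSolution(delta, phi2, phi2, converged, residual, branch)


def nonzero_branch_exists(params: NetworkParams, delta_in: float = 0.0,
                          delta_max: float = 25.0, n_grid: int = 200) -> bool:
    """Whether the self-consistency admits a nonzero solution.

    Checked by scanning ``F(Delta) - Delta`` on a log grid: a nonzero
    solution exists iff the map touches or crosses the diagonal at some
    ``Delta > 0``.  This avoids the critical slowing down of the damped
    iteration near the saddle-node.
    """
    grid = np.geomspace(1e-8, delta_max, n_grid)
    for d in grid:
        if _delta_map(params, float(d), delta_in) >= d:
            return True
    return False


def alpha_r_fp_star(g_h: float, alpha_z: float = 0.0, tau_z: float = 1.0,
                    tau_r: float = 1.0, window: tuple = (0.0, 40.0),
                    resolution: float = 1e-3) -> Optional[float]:
    """Smallest output-gate gain at which nonzero fixed points appear.

    Bias-free setting.  Returns ``None`` when no finite threshold exists in
    the search window (below the left critical gain ``sqrt(2)`` the
    saddle-node never happens at finite ``alpha_r``); returns 0.0 when a
    nonzero solution already exists at ``alpha_r = 0`` (``g_h > 2``).
    Located by bisection on the existence indicator.
    """

    def make(ar):
        return NetworkParams(n_units=2, g_h=g_h, alpha_z=alpha_z, alpha_r=ar,
                             tau_z=tau_z, tau_r=tau_r)

    lo, hi = window
    if nonzero_branch_exists(make(lo)):
        return float(lo)
    if not nonzero_branch_exists(make(hi)):
        return None
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if nonzero_branch_exists(make(mid)):
            hi = mid
        else:
            lo = mid
    return float(hi)


def fixed_point_table(g_h_values, alpha_r_values, branch: str = "nonzero",
                      **solver_kw):
    """Mean-field solutions on a (g_h, alpha_r) grid as a table.

    One row per grid point with the three variances, branch label and
    residual — the delimited-text export surface for phase-boundary work.
    """
    import pandas as pd

    rows = []
    for g in g_h_values:
        for ar in alpha_r_values:
            p = NetworkParams(n_units=2, g_h=float(g), alpha_r=float(ar))
            sol = solve_fixed_point(p, branch, **solver_kw)
            rows.append({"g_h": float(g), "alpha_r": float(ar),
                         "delta_h": sol.delta_h, "delta_z": sol.delta_z,
                         "delta_r": sol.delta_r, "branch": sol.branch,
                         "converged": sol.converged, "residual": sol.residual})
    return pd.DataFrame(rows)


def moments_at_fixed_point(params: NetworkParams, sol: MFTSolution,
                           delta_in: float = 0.0) -> StateMoments:
    """Gaussian moments of the state functions at a mean-field fixed point.

    These feed the spectral-curve equation and the stability criteria.  The
    h-average uses the total variance ``Delta_h`` (which already includes
    any quenched-input contribution); the gate drives are Gaussian with
    variance ``<phi^2>``.  For a binary update gate (``alpha_z = inf``) the
    z-average is carried as the open-gate fraction.
    """
    p = params
    dh, dz, dr = sol.delta_h, sol.delta_z, sol.delta_r
    phi2 = gaussian_average(lambda h: activation(h, p.g_h, p.beta_h) ** 2, dh)
    dphi2 = gaussian_average(lambda h: activation_deriv(h, p.g_h, p.beta_h) ** 2, dh)
    sr2 = gaussian_average(lambda r: gate_value(r, p.alpha_r, p.beta_r) ** 2, dr)
    dsr2 = gaussian_average(lambda r: gate_deriv(r, p.alpha_r, p.beta_r) ** 2, dr)
    sz_mean = gaussian_average(lambda z: gate_value(z, p.alpha_z, p.beta_z), dz)
    if math.isinf(p.alpha_z):
        # 0/1-valued gate: sigma^2 = sigma exactly (quadrature of the step
        # function would miscount the discontinuity)
        sz2 = sz_mean
    else:
        sz2 = gaussian_average(
            lambda z: np.asarray(gate_value(z, p.alpha_z, p.beta_z)) ** 2, dz)
    if math.isinf(p.alpha_r):
        sr2 = gaussian_average(lambda r: gate_value(r, p.alpha_r, p.beta_r), dr)
        dsr2 = 0.0
    return StateMoments(
        phi2=phi2, dphi2=dphi2, sr2=sr2, dsr2=dsr2,
        sz_mean=sz_mean, sz2=sz2,
        h2=dh, z2=dz, r2=dr,
        alpha_z=p.alpha_z, beta_z=p.beta_z, tau_z=p.tau_z, tau_r=p.tau_r,
        binary_z=math.isinf(p.alpha_z),
        z_mean=0.0, z_var=dz,
        at_fixed_point=True,
    )
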