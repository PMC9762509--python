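"""Jacobian spectra of the gated RNN and their random-matrix prediction.

The instantaneous Jacobian of the full 3N-dimensional flow is a structured
block matrix mixing the three Gaussian coupling matrices with diagonal
state-dependent factors.  In the large-N limit the boundary of its
eigenvalue support (the *spectral curve*) is predicted by non-Hermitian
random-matrix theory in terms of a handful of population moments: the set
of complex ``lambda`` with

    <phi'^2> ( <sigma_r^2> + <phi^2><sigma_r'^2> / |1 + tau_r lambda|^2 )
        * < sigma_z^2 / |lambda + sigma_z|^2 >_z  =  1.

Everything here consumes :class:`~gatedrnn.network.StateMoments`, which may
come either from the static mean-field theory (fixed points) or from
empirical steady-state averages of a simulation.

Two special structures matter for comparing against empirical spectra:

* whenever a gate field does not couple back into the dynamics (output
  gate with ``<phi^2><sigma_r'^2> = 0``, update gate at a fixed point or
  with ``alpha_z in {0, inf}``), the corresponding block contributes an
  exact N-fold eigenvalue atom at ``-1/tau``;
* for a binary update gate a finite fraction ``1 - <sigma_z>`` of
  eigenvalues sits exactly at the origin and the rest occupy a disk
  centered at -1 -- the marginally stable configuration when the disk
  radius stays below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import GatedNetwork, StateMoments
from .params import gate_value

__all__ = [
    "SpectralResult",
    "instantaneous_jacobian",
    "empirical_spectrum",
    "curve_values",
    "spectral_curve",
    "fp_unstable",
    "marginal_stability_radius",
    "limiting_density_infinite_alpha_z",
    "predicted_atoms",
    "fraction_inside",
    "near_zero_fraction",
    "pinching_diagnostic",
]


def _unpack_state(net: GatedNetwork, state):
    n = net.n
    if isinstance(state, (tuple, list)):
        h, z, r = (np.asarray(x, dtype=float) for x in state)
    else:
        flat = np.asarray(state, dtype=float)
        if flat.size != 3 * n:
            raise ValueError(f"state length {flat.size} != 3N = {3 * n}")
        h, z, r = flat[:n], flat[n:2 * n], flat[2 * n:]
    if len(h) != n or len(z) != n or len(r) != n:
        raise ValueError("state component length must equal N")
    return h, z, r


def instantaneous_jacobian(net: GatedNetwork, state) -> np.ndarray:
    """Dense 3N x 3N Jacobian of the gated RNN flow at a state.

    Block structure (rows = d/dt of h, z, r; columns = h, z, r):

        [ [sz](-1 + J_h [phi' sr])   diag(D)     [sz] J_h [phi sr'] ]
        [ J_z [phi'] / tau_z         -1/tau_z    0                  ]
        [ J_r [phi'] / tau_r         0           -1/tau_r           ]

    where ``D_i = sigma_z'(z_i) (-h_i + (J_h (phi * sr))_i)`` vanishes at
    fixed points.
    """
    n = net.n
    p = net.params
    h, z, r = _unpack_state(net, state)
    phi, dphi = net.phi(h), net.dphi(h)
    sr, dsr = net.sigma_r(r), net.dsigma_r(r)
    sz, dsz = net.sigma_z(z), net.dsigma_z(z)
    drive = net.J_h @ (phi * sr)

    J = np.zeros((3 * n, 3 * n))
    hh = net.J_h * (dphi * sr)[None, :]
    hh[np.diag_indices(n)] -= 1.0
    J[:n, :n] = sz[:, None] * hh
    J[:n, n:2 * n] = np.diag(dsz * (-h + drive))
    J[:n, 2 * n:] = sz[:, None] * (net.J_h * (phi * dsr)[None, :])
    J[n:2 * n, :n] = net.J_z * (dphi / p.tau_z)[None, :]
    J[n:2 * n, n:2 * n] = -np.eye(n) / p.tau_z
    J[2 * n:, :n] = net.J_r * (dphi / p.tau_r)[None, :]
    J[2 * n:, 2 * n:] = -np.eye(n) / p.tau_r
    return J


def empirical_spectrum(jacobian: np.ndarray) -> np.ndarray:
    """All eigenvalues of a (finite) Jacobian, unsorted."""
    jacobian = np.asarray(jacobian)
    if not np.all(np.isfinite(jacobian)):
        raise FloatingPointError("non-finite entries in the Jacobian")
    return np.linalg.eigvals(jacobian)


# --------------------------------------------------------------------------
# the spectral-curve equation
# --------------------------------------------------------------------------

def _z_gate_atoms(moments: StateMoments, n_bins: int = 201):
    """Discretize the update-gate distribution as (sigma value, weight) atoms.

    The lambda-dependent z-average in the curve equation is evaluated as a
    weighted sum over these atoms.  Binary gate: two atoms at 0 and 1;
    Gaussian z-field: values of sigma_z at Gauss-Hermite nodes; empirical
    z-samples: histogram of sigma_z values.
    """
    if moments.binary_z:
        f = moments.sz_mean
        return np.array([0.0, 1.0]), np.array([1.0 - f, f])
    if moments.z_samples is not None and len(moments.z_samples) > 0:
        s = np.asarray(gate_value(moments.z_samples, moments.alpha_z, moments.beta_z))
        hist, edges = np.histogram(s, bins=n_bins, range=(0.0, 1.0))
        mids = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        return mids[keep], hist[keep] / hist.sum()
    if moments.z_var > 0:
        from numpy.polynomial.hermite_e import hermegauss
        x, w = hermegauss(101)
        w = w / w.sum()
        s = np.asarray(gate_value(moments.z_mean + math.sqrt(moments.z_var) * x,
                                  moments.alpha_z, moments.beta_z))
        return s, w
    s0 = float(np.asarray(gate_value(np.array([moments.z_mean]),
                                     moments.alpha_z, moments.beta_z))[0])
    return np.array([s0]), np.array([1.0])


def curve_values(moments: StateMoments, lam: np.ndarray) -> np.ndarray:
    """G(lambda) = lhs(curve equation) - 1, vectorized over complex lambda.

    ``G > 0`` inside the predicted spectral support, ``G < 0`` outside; the
    boundary is the zero level set.
    """
    lam = np.asarray(lam, dtype=complex)
    sig, w = _z_gate_atoms(moments)
    zavg = np.zeros(lam.shape, dtype=float)
    flat = lam.ravel()
    acc = np.zeros(flat.shape, dtype=float)
    for s, wk in zip(sig, w):
        if s == 0.0 or wk == 0.0:
            continue  # sigma_z = 0 atoms contribute nothing (zero numerator)
        acc += wk * (s * s) / np.abs(flat + s) ** 2
    zavg = acc.reshape(lam.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_term = moments.sr2 + moments.phi2 * moments.dsr2 / np.abs(1.0 + moments.tau_r * lam) ** 2
        out = moments.dphi2 * r_term * zavg - 1.0
    # the pole at lambda = -1/tau_r is interior to the support
    return np.where(np.isnan(out), np.inf, out)


@dataclass
class SpectralResult:
    """Predicted spectral boundary plus optional empirical eigenvalues."""

    boundary: list  # list of complex polylines (closed curves)
    leading_edge: float
    imag_intercept: float
    moments: StateMoments
    eigenvalues: Optional[np.ndarray] = None


def _bisect_real(f, a: float, b: float, tol: float = 1e-10, it: int = 200) -> float:
    fa, fb = f(a), f(b)
    if fa == 0:
        return a
    if fb == 0:
        return b
    if fa * fb > 0:
        raise ValueError("no sign change in bracket")
    for _ in range(it):
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0 or (b - a) < tol:
            return m
        if fa * fm < 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def spectral_curve(moments: StateMoments, re_range=(-2.5, 2.5), im_range=(-2.5, 2.5),
                   n_grid: int = 600, refine_tol: float = 1e-6) -> SpectralResult:
    """Trace the zero level set of the curve equation on a complex grid.

    Returns the boundary polylines (via marching squares with sub-cell
    refinement of the leading edge and imaginary-axis intercept by
    bisection), the leading edge ``max Re lambda`` over the boundary, and
    the largest ``|Im lambda|`` where the boundary crosses the imaginary
    axis (0 when it does not).
    """
    from skimage import measure

    re = np.linspace(*re_range, n_grid)
    im = np.linspace(*im_range, n_grid)
    RE, IM = np.meshgrid(re, im, indexing="ij")
    G = curve_values(moments, RE + 1j * IM)
    contours = measure.find_contours(G, 0.0)
    if not contours:
        return SpectralResult([], -math.inf, 0.0, moments)

    d_re = re[1] - re[0]
    d_im = im[1] - im[0]
    polylines = []
    for c in contours:
        lam = (re[0] + c[:, 0] * d_re) + 1j * (im[0] + c[:, 1] * d_im)
        polylines.append(lam)

    # leading edge: refine the rightmost boundary point by bisection along
    # its horizontal line (G decreases monotonically moving right of the
    # support there)
    all_pts = np.concatenate(polylines)
    i_max = int(np.argmax(all_pts.real))
    y0 = all_pts[i_max].imag
    x0 = all_pts[i_max].real

    def g_re(x):
        return float(curve_values(moments, np.array([x + 1j * y0]))[0])

    try:
        leading = _bisect_real(g_re, x0 - 2 * d_re, x0 + 2 * d_re, tol=refine_tol)
    except ValueError:
        leading = x0

    # imaginary-axis intercept: largest y >= 0 with G(iy) = 0
    ys = np.linspace(0.0, im_range[1], n_grid)
    gy = curve_values(moments, 1j * ys)
    sign_change = np.nonzero(np.sign(gy[:-1]) * np.sign(gy[1:]) < 0)[0]
    if len(sign_change) == 0:
        intercept = 0.0
    else:
        k = sign_change[-1]

        def g_im(y):
            return float(curve_values(moments, np.array([1j * y]))[0])

        intercept = _bisect_real(g_im, ys[k], ys[k + 1], tol=refine_tol)

    return SpectralResult(polylines, float(leading), float(intercept), moments)


def fp_unstable(moments: StateMoments) -> bool:
    """Instability criterion for a mean-field fixed point.

    ``<phi'^2>(<phi^2><sigma_r'^2> + <sigma_r^2>) > 1`` iff the leading
    edge of the fixed-point spectral curve is positive.  Equality counts as
    stable (deterministic tie rule; the transition point itself is
    measure-zero).
    """
    return moments.dphi2 * (moments.phi2 * moments.dsr2 + moments.sr2) > 1.0


def marginal_stability_radius(moments: StateMoments) -> float:
    """Radius of the bulk eigenvalue disk for a binary update gate.

    With ``alpha_z = inf`` the spectrum splits into ``N(1 - <sigma_z>)``
    zero modes plus a disk centered at -1 of radius
    ``rho^2 = a/2 + sqrt(4b + a^2)/2`` with
    ``a = <phi'^2><sigma_z><sigma_r^2>`` and
    ``b = <phi'^2><sigma_z><phi^2><sigma_r'^2>``.  The state is marginally
    stable iff ``rho < 1`` (the two components stay disconnected).
    """
    a = moments.dphi2 * moments.sz_mean * moments.sr2
    b = moments.dphi2 * moments.sz_mean * moments.phi2 * moments.dsr2
    rad2 = 0.5 * a + 0.5 * math.sqrt(4.0 * b + a * a)
    if rad2 < 0:
        raise FloatingPointError("negative squared radius (should be impossible)")
    return math.sqrt(rad2)


def limiting_density_infinite_alpha_z(f_z: float, f_h: float, g_h: float) -> dict:
    """Structure of the limiting Jacobian density for a binary update gate.

    ``f_z`` is the open-gate fraction and ``f_h`` the fraction of
    unsaturated activations.  Mass ``1 - f_z`` sits exactly at 0 (closed
    gates freeze their units), mass ``f_z (1 - f_h)`` at -1 (open gates
    with saturated activation relax at the bare rate), and the remaining
    mass ``f_z f_h`` fills a uniform disk centered at -1 whose radius is
    the effective coupling gain ``(g_h / 2) sqrt(f_z f_h)`` of the
    open-and-unsaturated sub-network (output gate at its midpoint).  The
    uniform-disk density is chosen so the total integrates to 1.
    """
    if not (0 <= f_z <= 1 and 0 <= f_h <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    w_disk = f_z * f_h
    radius = 0.5 * g_h * math.sqrt(w_disk)
    return {
        "weight_at_zero": 1.0 - f_z,
        "weight_at_minus_one": f_z * (1.0 - f_h),
        "disk_center": -1.0,
        "disk_radius": radius,
        "disk_weight": w_disk,
        "disk_density": (w_disk / (math.pi * radius ** 2)) if radius > 0 else 0.0,
    }


def predicted_atoms(moments: StateMoments) -> list:
    """Exact point masses accompanying the spectral curve.

    The curve equation describes the connected bulk; decoupled gate blocks
    additionally contribute N-fold eigenvalue atoms (see module docstring).
    """
    atoms = []
    if moments.phi2 * moments.dsr2 < 1e-12:
        atoms.append(-1.0 / moments.tau_r)
    if moments.at_fixed_point or moments.alpha_z == 0.0 or moments.binary_z:
        atoms.append(-1.0 / moments.tau_z)
    if moments.binary_z:
        atoms.append(0.0)
    return atoms


def fraction_inside(moments: StateMoments, eigenvalues: np.ndarray,
                    boundary_tol: float = 0.02, atom_tol: float = 0.02) -> float:
    """Fraction of empirical eigenvalues inside the predicted support.

    An eigenvalue counts as inside when ``G(lambda) >= 0``, when it lies
    within ``atom_tol`` of a predicted point mass, or when its estimated
    distance to the zero level set ``|G| / |grad G|`` is below
    ``boundary_tol`` (tolerance inflation for finite-N edge fluctuations).
    """
    lam = np.asarray(eigenvalues, dtype=complex)
    g = curve_values(moments, lam)
    inside = g >= 0
    for a in predicted_atoms(moments):
        inside |= np.abs(lam - a) < atom_tol
    out = ~inside
    if np.any(out):
        eps = 1e-4
        lo = lam[out]
        gx = (curve_values(moments, lo + eps) - curve_values(moments, lo - eps)) / (2 * eps)
        gy = (curve_values(moments, lo + 1j * eps) - curve_values(moments, lo - 1j * eps)) / (2 * eps)
        grad = np.hypot(gx, gy)
        dist = np.abs(g[out]) / np.maximum(grad, 1e-12)
        near = dist < boundary_tol
        idx = np.nonzero(out)[0]
        inside[idx[near]] = True
    return float(np.mean(inside))


def near_zero_fraction(eigenvalues: np.ndarray, delta: float = 0.05,
                       per_unit: bool = True, n_units: Optional[int] = None) -> float:
    """Fraction of eigenvalues with ``|lambda| < delta``.

    With ``per_unit=True`` the count is normalized by N (not 3N), matching
    the prediction of ``N (1 - <sigma_z>)`` near-zero modes for a switchlike
    update gate.
    """
    lam = np.asarray(eigenvalues)
    count = int(np.sum(np.abs(lam) < delta))
    if per_unit:
        n = n_units if n_units is not None else len(lam) // 3
        return count / n
    return count / len(lam)


def pinching_diagnostic(params, alpha_z_list: Sequence[float], delta: float = 0.05,
                        t_relax: float = 100.0, dt: float = 0.05,
                        burn_in: float = 0.5, n_grid: int = 400):
    """Track how a switchlike update gate pinches the spectral curve.

    For each ``alpha_z`` the network is simulated to a steady state, the
    empirical Jacobian spectrum and the moment-based spectral curve are
    computed, and the table reports the leading edge, the imaginary-axis
    intercept and the near-zero eigenvalue fraction (radius ``delta``,
    normalized by N).  An error-function form ``c0 erf(c1 alpha_z)`` is
    fitted to the near-zero fraction and its goodness of fit is reported
    (qualitative diagnostic; the constants are not calibrated quantities).
    """
    import pandas as pd
    from scipy.optimize import curve_fit
    from scipy.special import erf

    from .network import make_network, simulate, steady_state_moments

    rows = []
    for az in alpha_z_list:
        p = params.replace(alpha_z=az)
        net = make_network(p)
        traj = simulate(net, t_final=t_relax, dt=dt, record_every=4)
        mom = steady_state_moments(traj, burn_in)
        res = spectral_curve(mom, n_grid=n_grid)
        jac = instantaneous_jacobian(net, traj.final_state())
        eigs = empirical_spectrum(jac)
        rows.append({
            "alpha_z": az,
            "leading_edge": res.leading_edge,
            "imag_intercept": res.imag_intercept,
            "near_zero_fraction": near_zero_fraction(eigs, delta, n_units=p.n_units),
        })
    table = pd.DataFrame(rows)

    fit = {"c0": math.nan, "c1": math.nan, "rms_residual": math.nan}
    try:
        az = table["alpha_z"].to_numpy(dtype=float)
        y = table["near_zero_fraction"].to_numpy(dtype=float)
        popt, _ = curve_fit(lambda a, c0, c1: c0 * erf(c1 * a), az, y,
                            p0=(max(y.max(), 1e-3), 0.1), maxfev=10000)
        resid = y - popt[0] * erf(popt[1] * az)
        fit = {"c0": float(popt[0]), "c1": float(popt[1]),
               "rms_residual": float(np.sqrt(np.mean(resid ** 2)))}
    except Exception:
        pass
    table.attrs["erf_fit"] = fit
    return table
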