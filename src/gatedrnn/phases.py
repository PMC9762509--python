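"""Phase-diagram construction and the dynamical experiments.

Bias-free parameter space of the gated RNN splits into regions:

1. the zero fixed point is the only solution (global attractor);
2. the zero FP is stable but unstable fixed points have proliferated
   (a topological transition with no asymptotic dynamical signature);
3. the stable zero FP coexists with a spontaneously appearing chaotic set
   (reached from large-norm initial conditions; in finite networks the
   chaotic transients eventually collapse, with collapse times growing
   with N);
4. the zero FP is unstable and a chaotic attractor remains;
5. (overlay) a chaotic/unstable state that a binary update gate renders
   marginally stable.

The region-2/3 boundary (the discontinuous dynamical transition in the
output-gate gain) is located numerically from trajectory ensembles; the
fixed-point proliferation boundary comes from the static mean-field theory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import mft
from .network import (
    GatedNetwork,
    InputProtocol,
    make_network,
    population_variance,
    simulate,
    substream,
)
from .lyapunov import max_lyapunov
from .params import NetworkParams, gate_value
from .spectra import (
    fp_unstable,
    instantaneous_jacobian,
    marginal_stability_radius,
)

__all__ = [
    "PhasePoint",
    "ClassificationError",
    "classify_point",
    "chaos_vote",
    "marginal_window",
    "critical_gain_zero_fp",
    "alpha_r_dmft_star",
    "transient_time_scaling",
    "input_induced_chaos_scan",
    "biased_critical_line",
    "critical_gain_with_input",
    "integrator_experiment",
    "reset_experiment",
    "find_reset_threshold",
]

# vote rule for stochastic lambda_max sign calls
VOTE_TRIALS = 8
VOTE_MIN_POSITIVE = 6
VOTE_THRESHOLD = 0.02


class ClassificationError(RuntimeError):
    """Raised when the collected evidence for a phase point is inconsistent."""


@dataclass
class PhasePoint:
    g_h: float
    alpha_r: float
    alpha_z: float
    region: int
    marginal_overlay: bool
    evidence: dict


def critical_gain_zero_fp(beta_r: float = 0.0, bracket=(0.5, 8.0),
                          tol: float = 1e-6) -> float:
    """Gain at which the zero fixed point loses stability (bias-free: 2).

    Bisection on the fixed-point instability criterion evaluated at the
    zero fixed point; the output gate plays no role there because
    ``phi(0) = 0`` silences its derivative channel.
    """

    def unstable(g: float) -> bool:
        p = NetworkParams(n_units=2, g_h=g, beta_r=beta_r)
        mom = mft.moments_at_fixed_point(p, mft.solve_fixed_point(p, "zero"))
        return fp_unstable(mom)

    lo, hi = bracket
    if unstable(lo) or not unstable(hi):
        raise ValueError("bracket does not straddle the transition")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if unstable(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def marginal_window(alpha_r: float = 0.0, upper_bracket=(2.5, 12.0),
                    tol: float = 1e-6) -> tuple:
    """Gain window of marginal stability for a binary update gate.

    Bias-free network, ``alpha_z = inf``.  The lower edge is where the
    zero fixed point first destabilizes (below it the network is simply
    stable and marginality is moot); the upper edge is where the bulk
    eigenvalue disk of the nontrivial state touches the origin, found by
    solving the static mean field jointly with the disk-radius condition
    ``rho = 1`` by bisection in the gain.
    """
    lower = critical_gain_zero_fp(tol=tol)

    def rho(g: float) -> float:
        p = NetworkParams(n_units=2, g_h=g, alpha_r=alpha_r, alpha_z=math.inf)
        sol = mft.solve_fixed_point(p, "nonzero")
        return marginal_stability_radius(mft.moments_at_fixed_point(p, sol))

    lo, hi = upper_bracket
    if rho(lo) >= 1.0 or rho(hi) <= 1.0:
        raise ValueError("upper bracket does not straddle rho = 1")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if rho(mid) < 1.0:
            lo = mid
        else:
            hi = mid
    return lower, 0.5 * (lo + hi)


def _chaos_init_scale(params: NetworkParams) -> float:
    """Initial-condition scale for chaotic-set detection.

    The chaotic set coexists with a stable fixed point whose basin would
    capture small initial conditions, so trajectories start at a norm
    comparable to the nonzero mean-field scale (floored at 1).
    """
    sol = mft.solve_fixed_point(params, init_branch="nonzero")
    return max(math.sqrt(max(sol.delta_h, 0.0)), 1.0)


def chaos_vote(params: NetworkParams, n_trials: int = VOTE_TRIALS,
               t_total: float = 150.0, t_transient: float = 40.0,
               dt: float = 0.05, seed: Optional[int] = None,
               collapse_var: float = 1e-9) -> dict:
    """Ensemble test for sustained chaos from large-norm initial conditions.

    Each trial draws its own couplings and initial condition from the
    ``trials`` substream, simulates, and estimates the maximal Lyapunov
    exponent over the observation window.  A trial whose activity has
    already collapsed onto the zero FP (population variance below
    ``collapse_var``) is scored with the zero-FP relaxation rate instead of
    wasting a tangent integration.  The call is "chaotic" when at least
    ``VOTE_MIN_POSITIVE`` of ``n_trials`` exponents exceed
    ``VOTE_THRESHOLD``.
    """
    root = params.seed if seed is None else seed
    scale = _chaos_init_scale(params)
    lams = []
    # same 6-of-8 supermajority fraction for any trial count
    needed = math.ceil(n_trials * VOTE_MIN_POSITIVE / VOTE_TRIALS)
    for i in range(n_trials):
        # early exit once the vote outcome is decided
        n_pos_so_far = sum(1 for l in lams if l > VOTE_THRESHOLD)
        remaining = n_trials - i
        if n_pos_so_far >= needed or n_pos_so_far + remaining < needed:
            break
        rng = substream(root, "trials", i)
        trial_seed = int(rng.integers(0, 2 ** 31 - 1))
        p = params.replace(seed=trial_seed)
        net = make_network(p)
        n = p.n_units
        init = (rng.normal(0, scale, n), rng.normal(0, scale, n), rng.normal(0, scale, n))
        probe = simulate(net, t_final=t_transient, dt=dt, initial_state=init,
                         record_every=8)
        if population_variance(probe)[-1] < collapse_var:
            # collapsed: relaxation rate of the zero FP (leading edge)
            lams.append(-abs(1.0 - params.g_h / 2.0) / 2.0)
            continue
        lam = max_lyapunov(net, t_total=t_total, t_transient=0.0, dt=dt,
                           initial_state=probe.final_state(), seed=trial_seed)
        lams.append(lam)
    lams = np.asarray(lams)
    n_pos = int(np.sum(lams > VOTE_THRESHOLD))
    return {
        "lambda_max": lams,
        "n_positive": n_pos,
        "chaotic": n_pos >= needed,
        "median_lambda": float(np.median(lams)),
    }


def classify_point(params: NetworkParams, n_trials: int = VOTE_TRIALS,
                   t_total: float = 120.0, seed: Optional[int] = None,
                   run_ensemble: bool = True) -> PhasePoint:
    """Classify a bias-free parameter point into regions 1-5.

    Combines (i) the fixed-point instability criterion on the zero FP,
    (ii) existence of nonzero mean-field solutions, (iii) an ensemble
    Lyapunov estimate from large-norm initial conditions, and (iv) the
    binary-gate marginal-stability condition for the region-5 overlay.
    Inconsistent evidence raises :class:`ClassificationError` rather than
    silently mislabeling.
    """
    p = params
    if p.beta_h or p.beta_z or p.beta_r:
        raise ValueError("region semantics are defined for the bias-free network")

    zero_mom = mft.moments_at_fixed_point(p, mft.solve_fixed_point(p, "zero"))
    zero_unstable = fp_unstable(zero_mom)
    nonzero_exists = mft.nonzero_branch_exists(p)

    vote = None
    if run_ensemble:
        vote = chaos_vote(p, n_trials=n_trials, t_total=t_total, seed=seed)

    if zero_unstable:
        region = 4
        # lambda_max can be small just above the transition, so only a
        # clearly negative ensemble contradicts the spectral evidence
        if vote is not None and vote["median_lambda"] < -VOTE_THRESHOLD:
            raise ClassificationError(
                f"zero FP unstable but ensemble median lambda_max is "
                f"{vote['median_lambda']:.3f}: inconsistent evidence")
    elif vote is not None and vote["chaotic"]:
        if not nonzero_exists:
            raise ClassificationError(
                "sustained chaos without any nonzero mean-field solution")
        region = 3
    elif nonzero_exists:
        region = 2
    else:
        region = 1

    # region-5 overlay: would a binary update gate make this state marginal?
    overlay = False
    if region in (3, 4):
        p_inf = p.replace(alpha_z=math.inf)
        sol = mft.solve_fixed_point(p_inf, "nonzero")
        mom = mft.moments_at_fixed_point(p_inf, sol)
        overlay = marginal_stability_radius(mom) < 1.0

    return PhasePoint(
        g_h=p.g_h, alpha_r=p.alpha_r, alpha_z=p.alpha_z,
        region=region, marginal_overlay=overlay,
        evidence={
            "zero_fp_unstable": bool(zero_unstable),
            "nonzero_mft_exists": bool(nonzero_exists),
            "vote": None if vote is None else {
                "n_positive": vote["n_positive"],
                "median_lambda": vote["median_lambda"],
            },
        },
    )


def alpha_r_dmft_star(g_h: float, n_units: int = 400, window=(0.0, 12.0),
                      resolution: float = 0.1, n_trials: int = VOTE_TRIALS,
                      t_total: float = 120.0, alpha_z: float = 0.0,
                      seed: int = 0, dt: float = 0.05) -> Optional[float]:
    """Locate the discontinuous dynamical transition in the output-gate gain.

    For fixed ``g_h < 2`` the smallest ``alpha_r`` at which large-norm
    trajectory ensembles sustain chaos (vote rule) is found by bisection.
    Returns ``None`` when no transition lies inside the window.  The
    located threshold sits strictly above the fixed-point proliferation
    threshold: fixed points appear first, dynamics follow later.
    """

    def chaotic(ar: float) -> bool:
        p = NetworkParams(n_units=n_units, g_h=g_h, alpha_z=alpha_z, alpha_r=ar,
                          seed=seed)
        return chaos_vote(p, n_trials=n_trials, t_total=t_total, dt=dt)["chaotic"]

    lo, hi = window
    if chaotic(lo):
        return float(lo)
    if not chaotic(hi):
        return None
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if chaotic(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def transient_time_scaling(params: NetworkParams, n_list: Sequence[int],
                           trials: int = 8, t_max: float = 400.0,
                           collapse_var: float = 1e-8, dt: float = 0.05,
                           seed: Optional[int] = None):
    """Median chaotic-transient lifetimes as a function of network size.

    In the coexistence region finite networks eventually fall into the
    stable zero FP; the transient end is the first time the population
    variance of ``h`` drops below ``collapse_var`` (censored at ``t_max``).
    """
    import pandas as pd

    root = params.seed if seed is None else seed
    rows = []
    for n in n_list:
        scale = _chaos_init_scale(params.replace(n_units=n))
        times = []
        for i in range(trials):
            rng = substream(root, "trials", 1000 * n + i)
            p = params.replace(n_units=n, seed=int(rng.integers(0, 2 ** 31 - 1)))
            net = make_network(p)
            init = tuple(rng.normal(0, scale, n) for _ in range(3))
            traj = simulate(net, t_final=t_max, dt=dt, initial_state=init,
                            record_every=8)
            v = population_variance(traj)
            hit = np.nonzero(v < collapse_var)[0]
            times.append(traj.times[hit[0]] if len(hit) else t_max)
        times = np.asarray(times)
        rows.append({"N": n, "median_transient": float(np.median(times)),
                     "censored": int(np.sum(times >= t_max)), "trials": trials})
    table = pd.DataFrame(rows)
    med = table["median_transient"].to_numpy()
    table.attrs["monotone_increasing"] = bool(np.all(np.diff(med) >= 0))
    if table["censored"].iloc[0] == table["trials"].iloc[0]:
        raise RuntimeError("no trajectory collapsed at the smallest N within budget")
    return table


def input_induced_chaos_scan(points: Sequence[tuple], sigma_h: float = 0.5,
                             n_units: int = 400, n_trials: int = 4,
                             t_total: float = 120.0, t_transient: float = 40.0,
                             dt: float = 0.05, seed: int = 0):
    """Compare lambda_max with and without a static random input on h.

    ``points`` is a sequence of ``(g_h, alpha_r)`` or
    ``(g_h, alpha_r, alpha_z)``.  Per point and trial a frozen i.i.d.
    ``N(0, sigma_h^2)`` input vector is applied to the h equation (gates
    receive none) and the maximal Lyapunov exponent is estimated with and
    without it, starting from a small initial condition (the "stable
    system" sits at its fixed point).  Verdicts: "induced" when the median
    exponent flips sign from negative to positive, "suppressed" when it
    flips the other way or drops by more than 0.02, otherwise "neutral".
    ``sigma_h = 0`` is neutral by construction.
    """
    import pandas as pd

    rows = []
    for point in points:
        g_h, alpha_r = point[0], point[1]
        alpha_z = point[2] if len(point) > 2 else 0.0
        lam0, lam1 = [], []
        base = NetworkParams(n_units=n_units, g_h=g_h, alpha_r=alpha_r,
                             alpha_z=alpha_z, seed=seed)
        for i in range(n_trials):
            rng = substream(seed, "trials", 17 + i)
            p = base.replace(seed=int(rng.integers(0, 2 ** 31 - 1)))
            net = make_network(p)
            init = tuple(rng.normal(0, 0.1, n_units) for _ in range(3))
            lam0.append(max_lyapunov(net, t_total=t_total, t_transient=t_transient,
                                     dt=dt, initial_state=init))
            if sigma_h > 0:
                inp = [InputProtocol.gaussian_static("h", n_units, sigma_h,
                                                     substream(p.seed, "input"))]
            else:
                inp = []
            lam1.append(max_lyapunov(net, t_total=t_total, t_transient=t_transient,
                                     dt=dt, inputs=inp, initial_state=init))
        m0, m1 = float(np.median(lam0)), float(np.median(lam1))
        if sigma_h == 0:
            verdict = "neutral"
        elif m0 < 0.0 < m1:
            verdict = "induced"
        elif (m1 < 0.0 < m0) or (m1 < m0 - VOTE_THRESHOLD):
            verdict = "suppressed"
        else:
            verdict = "neutral"
        rows.append({"g_h": g_h, "alpha_r": alpha_r, "alpha_z": alpha_z,
                     "lambda_no_input": m0, "lambda_with_input": m1,
                     "verdict": verdict})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# critical line with quenched static input
# --------------------------------------------------------------------------

def _biased_moments(g_h: float, alpha_r: float, sigma_h: float,
                    beta_z: float = 0.0):
    """Mean-field moments of the input-pinned fixed point.

    Static input ``I^h ~ N(0, sigma_h^2)`` enters the fixed-point condition
    as ``h = R + I/sigma_z``; in the zero-update-gain closure
    ``sigma_z = sigma_z(0)`` exactly, so the quenched input adds
    ``(sigma_h / sigma_z(0))^2`` to the h-variance.  The solver is seeded
    at the input floor so it lands on the input-pinned (smallest) solution
    branch.
    """
    s0 = float(np.asarray(gate_value(np.array([0.0]), 0.0, beta_z))[0])
    delta_in = (sigma_h / s0) ** 2 if sigma_h else 0.0
    p = NetworkParams(n_units=2, g_h=g_h, alpha_z=0.0, alpha_r=alpha_r,
                      beta_z=beta_z)
    if delta_in == 0.0:
        sol = mft.solve_fixed_point(p, "zero")
    else:
        sol = mft.solve_fixed_point(p, "nonzero", init_delta=delta_in,
                                    delta_in=delta_in)
    return mft.moments_at_fixed_point(p, sol, delta_in=delta_in)


def biased_critical_line(sigma_h: float, g_h_grid: Sequence[float],
                         alpha_r_max: float = 20.0, resolution: float = 1e-3):
    """Critical output-gate gain vs activation gain under static input.

    For each ``g_h`` the locus where the fixed-point instability criterion
    reaches equality under the input-pinned mean-field solution is found by
    bisection in ``alpha_r``; entries are 0 when the point is already
    unstable with ``alpha_r = 0`` (to the right of the continuous
    transition) and NaN when no instability occurs up to ``alpha_r_max``.
    """
    import pandas as pd

    def unstable(g, ar):
        return fp_unstable(_biased_moments(g, ar, sigma_h))

    rows = []
    for g in g_h_grid:
        if unstable(g, 0.0):
            rows.append({"g_h": g, "alpha_r_critical": 0.0})
            continue
        if not unstable(g, alpha_r_max):
            rows.append({"g_h": g, "alpha_r_critical": math.nan})
            continue
        lo, hi = 0.0, alpha_r_max
        while hi - lo > resolution:
            mid = 0.5 * (lo + hi)
            if unstable(g, mid):
                hi = mid
            else:
                lo = mid
        rows.append({"g_h": g, "alpha_r_critical": hi})
    return pd.DataFrame(rows)


def critical_gain_with_input(sigma_h: float, alpha_r: float = 0.0,
                             bracket=(0.5, 8.0), tol: float = 1e-6) -> float:
    """Critical ``g_h`` of the continuous transition at fixed ``alpha_r``."""

    def unstable(g):
        return fp_unstable(_biased_moments(g, alpha_r, sigma_h))

    lo, hi = bracket
    if unstable(lo) or not unstable(hi):
        raise ValueError("bracket does not straddle the transition")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if unstable(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# integrator and reset experiments
# --------------------------------------------------------------------------

class RegimeError(RuntimeError):
    """The requested experiment's dynamical regime is not present."""


def integrator_experiment(params: NetworkParams, input_strengths: Sequence[float] = (0.5, 1.0, 2.0),
                          t_relax: float = 50.0, t_on: float = 0.0, t_off: float = 10.0,
                          t_probe: float = 50.0, dt: float = 0.05,
                          slow_tol: float = 0.05, seed: Optional[int] = None):
    """Integration and retention of inputs along a slow Jacobian mode.

    With a switchlike update gate the Jacobian develops a cluster of
    near-zero eigenvalues whose eigenvectors span an approximate continuous
    attractor.  The network is relaxed, a slow mode (eigenvalue inside
    ``slow_tol``) with substantial weight on the h-block is extracted, and
    an input pulse along its eigenvector is applied on ``[t_on, t_off)``.
    The readout is the excess projection of the state onto the (unit) slow
    eigenvector, relative to an input-free run from the same state — the
    near-zero eigenvalues are quasi-degenerate at finite N, which makes
    the dual (left-eigenvector) basis ill-conditioned, so an orthogonal
    projector on the chosen mode is used instead.

    Retention(aligned) = projection at ``t_off + t_probe`` over projection
    at ``t_off``.  The misaligned control applies the same-strength input
    along a random direction orthogonal to the mode; its retention is its
    late-time slow-mode content relative to the aligned response at
    ``t_off`` (how much trace a generic input leaves on the slow mode).
    """
    import scipy.linalg

    net = make_network(params)
    n = params.n_units
    relax = simulate(net, t_final=t_relax, dt=dt, record_every=8, seed=seed)
    state0 = relax.final_state()

    jac = instantaneous_jacobian(net, state0)
    w, vr = scipy.linalg.eig(jac)
    slow = np.nonzero(np.abs(w) < slow_tol)[0]
    if len(slow) == 0:
        closest = float(np.min(np.abs(w)))
        raise RegimeError(
            f"no Jacobian eigenvalue with |lambda| < {slow_tol} "
            f"(closest: {closest:.3f}); not in the slow-manifold regime")
    # the input drives the h equation, so the mode must live on the h-block
    h_weight = np.array([np.linalg.norm(np.real(vr[:n, i])) /
                         np.linalg.norm(vr[:, i]) for i in slow])
    i_slow = int(slow[np.argmax(h_weight)])
    v = np.real(vr[:, i_slow])
    v = v / np.linalg.norm(v)
    v_h = v[:n].copy()
    v_h = v_h / np.linalg.norm(v_h)

    t_end = t_off + t_probe + 10.0
    base = simulate(net, t_final=t_end, dt=dt, initial_state=state0, record_every=2)

    def run(direction, eps):
        inp = [InputProtocol("h", eps * direction, [(t_on, t_off)], tag="pulse")]
        traj = simulate(net, inputs=inp, t_final=t_end, dt=dt,
                        initial_state=state0, record_every=2)
        # h-block readout: the slow mode's gate components relax on the
        # gate timescales and only add cross-talk to the projection
        proj = np.abs((traj.h - base.h) @ v_h)
        return traj.times, proj

    rng = substream(params.seed if seed is None else seed, "input", 3)
    rand_dir = rng.normal(size=n)
    rand_dir -= (rand_dir @ v_h) * v_h
    rand_dir /= np.linalg.norm(rand_dir)

    out = {"eigenvalue": complex(w[i_slow]), "traces": {}, "retention": {}}
    i_off = i_probe = None
    p_al_off = None
    for eps in input_strengths:
        times, proj = run(v_h, eps)
        if i_off is None:
            i_off = int(np.searchsorted(times, t_off))
            i_probe = int(np.searchsorted(times, t_off + t_probe))
        out["traces"][("aligned", eps)] = (times, proj)
        out["retention"][("aligned", eps)] = float(proj[i_probe] / max(proj[i_off], 1e-300))
        if eps == max(input_strengths):
            p_al_off = float(proj[i_off])
    times, proj = run(rand_dir, max(input_strengths))
    out["traces"][("misaligned", max(input_strengths))] = (times, proj)
    out["retention"][("misaligned", max(input_strengths))] = float(
        proj[i_probe] / max(p_al_off, 1e-300))
    plateaus = [out["traces"][("aligned", eps)][1][i_off] for eps in input_strengths]
    out["plateau_vs_strength"] = dict(zip(input_strengths, map(float, plateaus)))
    return out


def reset_experiment(params: NetworkParams, mode: str = "z_pulse",
                     amplitude: float = 1.0, t_memory: float = 40.0,
                     pulse_duration: float = 20.0, t_after: float = 40.0,
                     dt: float = 0.05, seed: Optional[int] = None) -> dict:
    """Erase the memory trace of a marginally stable state through the gates.

    Two reset mechanisms:

    * ``"r_clamp"``: pin the output gate to zero for ``pulse_duration``;
      the recurrent drive vanishes and ``h`` relaxes to zero at the
      per-unit rate ``sigma_z``.
    * ``"z_pulse"``: a positive static input to the update gate raises the
      open-gate fraction, pushing the marginal state across the chaotic
      boundary; the transient chaos scrambles the state and erases the
      previous memory direction.  Sub-threshold pulses leave the memory
      intact.

    Returns the normalized projection of ``h(t)`` onto the pre-reset
    state, the final norm, and a success flag (post-reset projection below
    0.1).
    """
    net = make_network(params)
    n = params.n_units
    pre = simulate(net, t_final=t_memory, dt=dt, record_every=4, seed=seed)
    state0 = pre.final_state()
    h_ref = state0[0] / np.linalg.norm(state0[0])

    if mode == "r_clamp":
        clamped = GatedNetwork(params=params, J_h=net.J_h, J_z=net.J_z, J_r=net.J_r,
                               gate_override={**net.gate_override, "r": 0.0})
        mid = simulate(clamped, t_final=pulse_duration, dt=dt,
                       initial_state=state0, record_every=4)
        post = simulate(net, t_final=t_after, dt=dt,
                        initial_state=mid.final_state(), record_every=4)
        segs = [(pre, 0.0), (mid, t_memory), (post, t_memory + pulse_duration)]
    elif mode == "z_pulse":
        inp = [InputProtocol("z", amplitude * np.ones(n), [(0.0, pulse_duration)],
                             tag=f"z_pulse({amplitude})")]
        post = simulate(net, inputs=inp, t_final=pulse_duration + t_after, dt=dt,
                        initial_state=state0, record_every=4)
        segs = [(pre, 0.0), (post, t_memory)]
    else:
        raise ValueError(f"unknown reset mode {mode!r}")

    times, proj, norms = [], [], []
    for traj, offset in segs:
        nh = np.linalg.norm(traj.h, axis=1)
        pr = np.abs(traj.h @ h_ref) / np.maximum(nh, 1e-300)
        times.append(traj.times + offset)
        proj.append(pr)
        norms.append(nh)
    times = np.concatenate(times)
    proj = np.concatenate(proj)
    norms = np.concatenate(norms)
    final_proj = float(proj[-1])
    return {
        "times": times, "projection": proj, "h_norm": norms,
        "final_projection": final_proj, "final_norm": float(norms[-1]),
        "success": final_proj < 0.1, "mode": mode, "amplitude": amplitude,
    }


def find_reset_threshold(params: NetworkParams, bracket=(0.0, 2.0),
                         resolution: float = 0.05, **kwargs) -> Optional[float]:
    """Bisect the mean update-gate input needed for a successful reset."""
    lo, hi = bracket
    if reset_experiment(params, "z_pulse", amplitude=lo, **kwargs)["success"]:
        return float(lo)
    if not reset_experiment(params, "z_pulse", amplitude=hi, **kwargs)["success"]:
        return None
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if reset_experiment(params, "z_pulse", amplitude=mid, **kwargs)["success"]:
            hi = mid
        else:
            lo = mid
    return float(hi)
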