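"""Predict the Jacobian spectral boundary and compare with eigenvalues.

At a fixed point of the bias-free network the spectral support is a circle
|lambda + 1/2| = g_h / 4: its leading edge crosses the origin at g_h = 2,
the transition to chaos.  For the chaotic steady state the same curve
equation, fed with measured moments, still bounds the empirical spectrum.
"""

import numpy as np

from gatedrnn import NetworkParams, make_network, simulate, steady_state_moments
from gatedrnn.mft import moments_at_fixed_point, solve_fixed_point
from gatedrnn.spectra import (
    empirical_spectrum,
    fraction_inside,
    instantaneous_jacobian,
    spectral_curve,
)

# --- analytic circle at the zero fixed point -----------------------------
for g in (1.5, 2.0, 3.0):
    p = NetworkParams(n_units=2, g_h=g)
    mom = moments_at_fixed_point(p, solve_fixed_point(p, "zero"))
    res = spectral_curve(mom, n_grid=400)
    print(f"g_h={g:3.1f}: leading edge {res.leading_edge:+.4f} "
          f"(closed form {-0.5 + g / 4:+.4f})")
print("the edge hits zero at g_h = 2: the continuous transition to chaos\n")

# --- empirical spectrum of a chaotic network -----------------------------
p = NetworkParams(n_units=400, g_h=3.0, seed=2)
net = make_network(p)
traj = simulate(net, t_final=150.0, record_every=4)
mom = steady_state_moments(traj)
eigs = empirical_spectrum(instantaneous_jacobian(net, traj.final_state()))
frac = fraction_inside(mom, eigs)
print(f"chaotic state, N=400: {frac:.1%} of the 3N Jacobian eigenvalues lie")
print("inside the random-matrix boundary predicted from measured moments.")
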