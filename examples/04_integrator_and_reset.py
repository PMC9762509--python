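"""The marginal state as a working memory: integrate, retain, reset.

A switchlike update gate (alpha_z = 30) freezes roughly half the units,
creating a manifold of near-zero Jacobian modes.  Inputs aligned with a
slow mode are integrated and retained long after they end; misaligned
inputs leave no trace.  A positive pulse to the update gate re-opens the
frozen gates, briefly tips the network into chaos, and erases the stored
state.
"""

from gatedrnn import NetworkParams
from gatedrnn.phases import integrator_experiment, reset_experiment

# --- integrator ----------------------------------------------------------
p = NetworkParams(n_units=300, g_h=3.0, alpha_z=30.0, seed=12)
res = integrator_experiment(p, input_strengths=(0.2, 0.4))
print(f"slow eigenvalue used: |lambda| = {abs(res['eigenvalue']):.2e}")
for (cond, eps), ret in res["retention"].items():
    print(f"  {cond:10s} strength {eps}: retention at +50 time units = {ret:.3f}")
print("aligned pulses persist (retention near 1); misaligned ones vanish.\n")

# --- reset ---------------------------------------------------------------
pm = NetworkParams(n_units=400, g_h=3.0, alpha_r=2.5, alpha_z=100.0, seed=13)
for amp in (0.05, 1.5):
    r = reset_experiment(pm, "z_pulse", amplitude=amp, pulse_duration=30.0,
                         t_after=60.0)
    kind = "sub-threshold" if amp < 0.5 else "supra-threshold"
    print(f"{kind} update-gate pulse (mean {amp}): final overlap with the "
          f"pre-pulse state = {r['final_projection']:.3f}")
print("a strong pulse scrambles the state (overlap ~ 0): context-dependent reset.")
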