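# Methods

This note records the model conventions, numerical choices, and the design
decisions behind `gatedrnn`, in enough detail to reproduce or audit every
number the package computes.

## Model and conventions

The network is the continuous-time gated RNN described in the README: unit
states `h`, update-gate drives `z`, output-gate drives `r`, activation
`phi(x) = tanh(g_h x + beta_h)`, gates
`sigma(x) = [1 + exp(-alpha x + beta)]^(-1)`.  Time is measured in units of
the h time constant (1); the gate time constants `tau_z, tau_r` default
to 1.  Couplings are i.i.d. `N(0, 1/N)`, independent across the three
matrices.

Sign convention: the gate bias enters as `-alpha x + beta`, so a positive
`beta_r` *closes* the output gate at rest (`sigma_r(0) = 1/(1+e^{beta_r})`)
and the zero-fixed-point stability threshold generalizes to
`g_h = 1 + e^{+beta_r}`.  All headline results here are for the bias-free
network, where the threshold is exactly 2.

Infinite gate gain is an explicit flag (`math.inf`), interpreted as a
Heaviside step with value 1/2 exactly at threshold and zero pointwise
derivative.  For ODE runs that need smoothness the documented surrogate is
`alpha_z = 100`; the pinching of the spectral curve is exponentially fast
in `alpha_z`, so 100 is indistinguishable from the binary limit for every
diagnostic we compute.

## Integration

Fixed-step classical RK4 with default `dt = 0.05` (all time constants are
O(1)).  A fixed step is required by the tangent-space Lyapunov machinery;
halving `dt` changes endpoint norms of a T = 50 chaos-free run by well
under 1% (tested).  The flow is globally bounded (`sigma_z >= 0`, `phi`
and `sigma_r` bounded), so any non-finite state is reported as an
integrator error with the first bad time.  Default initial conditions are
i.i.d. `N(0, 0.1^2)` in all three blocks: small enough to stay in the zero
fixed point's basin when it is stable, nonzero so the measure-zero fixed
point itself is avoided.

All randomness derives from one root seed through named substreams
(couplings, initial conditions, inputs, trial ensembles), so every
stochastic experiment is bit-reproducible.

## Static mean-field theory

At a fixed point, `h_i = sum_j J^h_ij phi(h_j) sigma_r(r_j)` and
`x_i = sum_j J^x_ij phi(h_j)`; independence of the coupling matrices makes
the site variables independent zero-mean Gaussians with

    Delta_z = Delta_r = <phi^2>_{Delta_h},
    Delta_h = <phi^2>_{Delta_h} * <sigma_r^2>_{Delta_r}.

Gaussian averages use 101-node Gauss-Hermite quadrature (absolute accuracy
~1e-6 for these bounded integrands; verified by node doubling).  For
binary gates the quadrature would miscount the step discontinuity, so
`<sigma_z>` uses the symmetric tie rule and `<sigma_z^2> = <sigma_z>`
exactly.  The self-consistency is solved by damped fixed-point iteration
(damping 0.5, tolerance 1e-10, at most 10^4 iterations); the nonzero
branch is seeded at `Delta_h = 1` and classified nonzero when the
converged value exceeds 1e-6.

Near the saddle-node where nonzero solutions appear, the iteration slows
critically, so *existence* is decided separately by scanning
`F(Delta) - Delta` on a 200-point log grid over [1e-8, 25]: a nonzero
solution exists iff the map touches the diagonal.  `alpha_r,FP*(g_h)` is
then a bisection on this indicator (window [0, 40], resolution 1e-3).
The closure was validated against simulation: at `g_h = 3` the chaotic
population variance at N = 500 matches `Delta_h` to 0.3%, and across five
supercritical parameter points the discrepancy stays within 10%.

Under quenched static input `I^h ~ N(0, sigma_h^2)` the fixed-point
condition becomes `h = R + I/sigma_z`; in the zero-update-gain closure
(`sigma_z = sigma_z(0)` exactly) this adds `(sigma_h/sigma_z(0))^2` to
`Delta_h`.  The biased critical line is the locus where the instability
criterion reaches equality on this input-pinned solution.  Finite networks
can settle into atypical stable fixed points somewhat beyond this line
(they self-organize to measured criterion values just under 1), so the
line is a mean-field boundary, not a finite-N simulation prediction.

## Spectral theory

The spectral curve is evaluated as the zero level set of

    G(lambda) = <phi'^2> ( <sigma_r^2>
                + <phi^2><sigma_r'^2> / |1 + tau_r lambda|^2 )
                * < sigma_z^2 / |lambda + sigma_z|^2 >_z  -  1,

with `G > 0` inside the support.  The lambda-dependent z-average is
computed over discrete `(sigma_z, weight)` atoms: the two-point {0, 1} law
for a binary gate, gate values at Gauss-Hermite nodes for a Gaussian
z-field, or a 201-bin histogram of measured z-samples for simulation
states.  Curves are traced by marching squares on a 600x600 grid over
[-2.5, 2.5]^2 (400 in tests), with the leading edge and the imaginary-axis
intercept refined by bisection to 1e-6.  The reading of the two moduli
denominators is pinned by a standing test: at the bias-free zero fixed
point the equation must reduce to the circle `|lambda + 1/2| = g_h/4`,
whose edge crosses zero at `g_h = 2`.

Whenever a gate block does not couple back into the dynamics the curve
equation cannot see its eigenvalues, which sit in exact N-fold atoms:
at `-1/tau_r` when `<phi^2><sigma_r'^2> = 0` (fixed points, or
`alpha_r = 0`), at `-1/tau_z` at fixed points or when `sigma_z' == 0`
(`alpha_z` zero or infinite), and at 0 for the binary update gate (the
frozen modes, `N(1 - <sigma_z>)` of them).  The empirical-vs-predicted
comparison (`fraction_inside`) therefore counts an eigenvalue as inside
when `G >= 0`, when it is within 0.02 of a predicted atom, or when its
estimated distance to the boundary `|G|/|grad G|` is below 0.02 — the last
term absorbs the O(N^{-1/2}) edge fluctuations of finite matrices.

For the binary update gate the bulk is a disk centered at -1 with
`rho^2 = a/2 + sqrt(4b + a^2)/2`, `a = <phi'^2><sigma_z><sigma_r^2>`,
`b = <phi'^2><sigma_z><phi^2><sigma_r'^2>`; marginal stability is
`rho < 1`.  The limiting eigenvalue density is reported as mass `1 - f_z`
at 0, `f_z(1 - f_h)` at -1, and a uniform disk of weight `f_z f_h`; we
resolve the disk normalization by giving it radius
`(g_h/2) sqrt(f_z f_h)` (the effective gain of the open-and-unsaturated
subnetwork with the output gate at its midpoint) and density
`weight/(pi R^2)`, which integrates to 1 and matches the empirical
zero-cluster count at `alpha_z = 100` to within 5 points of N.

### Marginal window

Solving the mean field jointly with `rho = 1` at `alpha_z = inf`,
`alpha_r = 0`, no biases, gives the marginally stable window
`2 < g_h < 6.486` (bisection to 1e-8 on top of the quadrature).  The
window's upper edge is sensitive to `Delta_h`: a 4% change moves it by
~0.3.  Direct simulation at `alpha_z = 100` puts the empirical loss of
marginality between 6.0 and 6.5 but is glassy — the dynamics settle into
frozen configurations in which the realized gate pattern is correlated
with the state, which the annealed (independent z) theory cannot capture —
so the theoretical value 6.486 is reported as computed rather than tuned
to the simulations.

## Lyapunov analysis

Benettin/QR: k tangent vectors are co-integrated with the trajectory (the
tangent RK4 stages use the Jacobian at the matching state stages, in block
matrix-vector form, never materializing the 3N x 3N matrix),
reorthonormalized every 1.0 time units, after 200 time units of state
transient *and* 10 reorthonormalization blocks of tangent warm-up — the
warm-up removes the O(1%) downward bias from the random basis's decaying
components on O(100)-time runs.  Defaults follow the convergence checks in
the tests: halving the reorthonormalization interval moves the top ten
exponents by <0.01, and the full-spectrum sum matches the time-averaged
Jacobian trace to 2%.

Kaplan-Yorke: `D_A = M + (sum_{i<=M} lambda_i)/|lambda_{M+1}|` with M the
largest index with nonnegative partial sum; 0 when even `lambda_1 < 0`; an
error instructs the caller to compute more exponents when M is not
bracketed.

### Mean-field lambda_max

For `alpha_z = 0` the h-field is Gaussian and Price's theorem closes the
variational derivatives of correlators into plain correlation functions.
Site-wise independence of h and r (independent coupling matrices) lets the
product-field derivative factorize:
`dC_{phi sigma_r}/dC_h = C_{phi'} C_{sigma_r}` and
`dC_{phi sigma_r}/dC_r = C_phi C_{sigma_r'}`; the h-r cross-susceptibility
is dropped on the same independence grounds.  The resulting system,

    [(<sigma_z> + kappa)^2 - d^2/dtau^2] chi_h
        = <sigma_z^2> [C_phi' C_sr chi_h + C_phi C_sr' chi_r],
    [(1 + tau_r kappa)^2 - tau_r^2 d^2/dtau^2] chi_r = C_phi' chi_h,

is discretized on the symmetric lag grid (lag spacing 4*dt, window
[-20, 20], Dirichlet ends — the susceptibilities decay well inside the
window in the tested regimes), and the quadratic-in-kappa pencil is solved
by companion linearization; the largest real eigenvalue is the mean-field
`lambda_max`.  At a fixed point (constant correlators) this reduces to
`kappa = g_h/4 - 1/2`, exactly the spectral-curve leading edge — the
standing consistency check.  For `alpha_z > 0` the closure is refused: the
h-distribution becomes strongly non-Gaussian and Price's theorem has no
justification there.

Correlators are measured from simulation by FFT over time origins,
averaged over units, on the post-burn-in window (required to exceed 10x
the maximum lag); a failed stationarity check flags rather than fails the
result.  Stationarity itself is judged by comparing the mean population
variance over the third and fourth quarters of a run (relative difference
below 20%).

## Phase diagram and experiments

Region classification combines (i) the zero-FP criterion, (ii) nonzero
mean-field existence, (iii) a trajectory-ensemble Lyapunov vote, and
(iv) the binary-gate marginality condition as an overlay.  Chaotic-set
detection initializes at the nonzero mean-field scale (floored at norm 1
per unit) because small initial conditions would fall into the coexisting
stable fixed point's basin.  Sign calls use 8 trials with a "positive"
call at >= 6 exponents above +0.02 (the same supermajority fraction for
other trial counts, with early exit once decided).  Evidence
contradictions (e.g. an unstable zero FP with a clearly negative ensemble
median) raise an error rather than silently labeling.

The dynamical transition `alpha_r,DMFT*` is located by bisection of the
vote over `alpha_r`.  Its measured location drifts down with N — expected,
since the coexisting chaotic transients scale with system size — so
threshold and jump are always quoted at a stated N.  In the shipped tests:
located at N = 300 (resolution 3), jump measured at N = 600 with 5-trial
medians over 200 time units after a 120-unit settling probe (below the
transition the non-scaling transients die within it), giving a jump of
~0.13 between brackets at
`g_h = 1.9` against a smooth |lambda| < 0.06 crossing along the gain axis.
Scaled-down sizes throughout (N = 250-800 in tests, N = 600-1000 for
spot checks) were chosen as the smallest at which the corresponding
large-N statement is stable across seeds.

Input-induced chaos: at update-gate gain zero and input std 0.5 the
simulated input-pinned states sit at the edge of stability (criterion
values just under 1, lambda_max ~ 0 from below) at every size we tried up
to N = 1500, even where the mean-field line predicts instability; with a
moderately switchlike update gate (`alpha_z = 6`) the flip is robust
(`(g_h, alpha_r) = (1.9, 12)`: lambda_max from -0.03 without input to
+0.02..0.04 with it).  The shipped flip demonstration therefore uses the
`alpha_z = 6` point; the verdict is a sign flip of the median exponent.

Integrator: after relaxation the Jacobian is diagonalized, and among
eigenvalues with `|lambda| < 0.05` the mode with the largest h-block
weight is selected (the near-zero modes are quasi-degenerate at finite N,
which makes left-eigenvector duals ill-conditioned; the readout is
therefore the orthogonal projection of the excess h-state onto the mode's
h-direction, relative to an input-free twin run).  Aligned pulses of
moderate strength retain ~0.8 of their projection 50 time units after
offset with plateaus approximately linear in strength; misaligned pulses
leave <0.05.  Very weak pulses drown in the twin-run divergence noise and
very strong ones scramble the state nonlinearly — strengths 0.2-0.5 are
the documented operating range at N = 300.

Reset: mode (a) clamps the output gate to zero, draining `h` at the
per-unit rate `sigma_z` (uniform rate 1/2 at `alpha_z = 0`; frozen units
are untouched at large `alpha_z`); mode (b) applies a positive mean input
to the update gate of a marginal state (`g_h = 3, alpha_r = 2.5,
alpha_z = 100`), which raises the open-gate fraction, tips the state
chaotic for the pulse duration (30 time units in the tests), and leaves
the post-pulse overlap with the stored state below 0.1; sub-threshold
pulses (mean 0.05) leave it above 0.5.  The threshold search is a
bisection over pulse mean in [0, 2].

## What the synthetic conditions do and do not show

All inputs are generated internally: Gaussian coupling ensembles, Gaussian
or eigenvector-aligned static inputs, and parameter points chosen at the
phase-diagram landmarks.  Passing tests show that the implementation
reproduces the large-N theory of *this* ensemble — independent Gaussian
couplings, no autapse structure, no correlations between matrices, no
spatial or Dale-type structure — at sizes N = 250-1000.  They do not show
robustness to structured connectivity, to learned weights, or to
finite-size effects below N ~ 100, and the glassy multistability noted for
binary-gate states means single-trajectory diagnostics there depend on
history and seed.

## Known limitations

- The mean-field `lambda_max` is restricted to `alpha_z = 0` by
  construction (Price closure); the package deliberately refuses other
  values instead of extrapolating.
- The two-time correlators are measured from simulation, not solved as a
  self-consistent functional equation; there is no closed-form C(tau)
  solver.
- The marginal-window upper edge and the biased critical line are annealed
  mean-field statements; simulations show self-organized stabilization
  slightly beyond both (discussed above).
- `alpha_r,FP*` and `alpha_r,DMFT*` are located numerically; no closed
  forms are provided.
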