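# Methods

## Model and assumptions

The package implements a hybrid population model on the real line,
truncated to a symmetric grid: a within-season PDE

    du/dt = d/dx (D du/dx - q u) + f(x, u),   0 < t <= tau,

composed with a between-season impulse `u -> K * g(., u(tau, .))`.  The
structural assumptions mirror the standing hypotheses of the underlying
threshold theory: `f(x,0) = g(x,0) = 0`, `f(x,u)/u` and `g(x,u)/u`
nonincreasing in `u` (sub-homogeneity, which makes the positive steady
state unique), `g >= 0`, and a BB-type tail condition
`limsup eta * exp(limsup theta * tau) < 1` with `theta = d_u f(.,0)`,
`eta = d_u g(.,0)` — the favorable habitat is bounded and surrounded by
unfavorable regions, so solutions decay at spatial infinity.  Validators
check the ratio monotonicity on a sampled lattice (`u` in steps of 0.1 up
to 10, tolerance 1e-10) rather than symbolically; the tail condition is
evaluated from profile tails (constant tail for plateau profiles, the
extremum over one period for periodic ones, which is the correct
limsup/liminf for periodic functions).

The positive-invariance condition `L*exp(K*tau) <= 1` is *checked but not
enforced*: the canonical scenario constants (`K=0, L=2`) violate it while
the dynamics remain bounded (the Beverton–Holt birth saturates at
`sup r = 2` and the kernel averages, so iterates stay below 2); the check
therefore warns once per run instead of raising.

## Habitat profiles

Plateau profiles ramp linearly between a favorable core (`r = 2` on
`[-l, l]`; `alpha = 0` on `[-m, m]`) and a constant unfavorable tail
(`r = 1`, `alpha = 1` outside `[-2*scale, 2*scale]`).  Periodic profiles
repeat the same patch shape with period `5*scale`.  The ascending ramp of
each periodic profile is taken as the unique affine branch that makes the
profile continuous, periodic and range-consistent (`r1` in `[1,2]`,
`alpha1` in `[0,1]`); continuity is required by the standing assumptions,
and the package logs this choice once per run.

## Numerics

**Transport by sampled-kernel convolution.**  The linear part of the
season equation is advanced exactly by convolving with the advected heat
kernel — a Gaussian of mean `q*dt` and variance `2*D*dt` — sampled on
grid offsets over mean ± 8 sd and renormalized to unit mass.  This is
unconditionally stable, free of numerical dispersion at large drift
(`q = 15` poses no difficulty), and exact for constants.  The sampled
Gaussian requires `sd >= 0.75 * spacing`; below that the solver raises a
resolution error rather than alias.  Off-domain values are zero
(Dirichlet truncation, justified by the spatial decay of solutions under
the BB-type condition); a validator warns when the transport + dispersal
footprint exceeds half the domain half-width.  A periodic (circular
convolution) boundary mode exists for fully periodic habitats, where the
decay justification fails and the infinite-line solution is itself
periodic — there the circular domain commensurate with the habitat period
is the *exact* discretization.

**Reaction by closed forms.**  The logistic mortality
`du/dt = -alpha*u - u^2` is a Bernoulli equation with the closed-form
step `u -> alpha*u*e^{-alpha dt} / (alpha + u*(1 - e^{-alpha dt}))`
(limit `u/(1+u*dt)` at `alpha = 0`), applied nodewise; linear reactions
use the exact exponential factor; custom reactions take one classical
RK4 substep.

**Strang splitting.**  Half reaction, full transport, half reaction per
substep; default `dt = tau/64`.  With exact substeps the scheme is
second order in `dt` for smooth coefficients (observed order 2.0 on a
sigmoidal coefficient); the kinks of the piecewise-linear habitat
profiles reduce the observed order to about 1.5, which is a property of
the coefficients, not of the scheme.  Negative values produced by
roundoff (below 1e-12) are clipped and the clipped mass tracked; a step
aborts if clipping ever exceeds 1e-6 of the total mass.

**Generation map.**  The dispersal kernel is sampled on grid offsets
(window mean ± 8 sd, resolution guard `spacing < sd/2`), renormalized
once so its discrete integral is exactly 1, and applied by zero-padded
(or circular) discrete convolution.  Iteration records sup-norm and mass
every generation and fields every `record_every` (default 10); a
divergence guard aborts above sup-norm 1e6.  Fixed points are found by
direct iteration to a sup-norm tolerance (default 1e-8, cap 2000
generations), exploiting the global attractivity of the positive steady
state in persistent regimes.

**Spectral threshold.**  The linearized operator is assembled as a
structured product — kernel convolution matrix × diag(eta) × the
propagator obtained by binary exponentiation of the single-substep
splitting matrix — and its agreement with the composed matrix-free
application is a tested invariant (1e-10).  Truncation right-multiplies
by the tent cutoff `zeta_rho(x) = clip(rho - |x|, 0, 1)` and restricts to
the ball.  `rho_L` is estimated on a coarser "spectral grid"
(spacing ~0.2; the linearized kernel is smooth at that scale) with eight
radii geometrically spaced from 10 to 0.9× the half-width; the sweep is
declared plateaued when the relative change over the last three radii
drops below 1e-3.  Dense eigensolves are used up to 1025 nodes,
matrix-free power iteration above; the power iteration requires five
consecutive stable estimates before declaring convergence (a single
small step can occur mid-transient) and falls back to a dense solve on
non-convergence.  The substep for the spectral grid is chosen
automatically as the largest power-of-two division of `tau` whose
transport kernel is still resolved.

For the homogeneous oracle (`eta`, `theta` constant) the exact threshold
is `eta0 * exp(theta0 * tau)`; the sweep recovers it to ~0.15% at
half-width 80.  The approach to the `rho -> inf` limit is algebraic in
`rho` (the tent cutoff and the ball restriction cost O(1/rho^2)), so the
plateau criterion is a heuristic, not a certificate.

## Scenario suite and classification

Scenario builders reproduce the reference simulation grids: drift
`q ∈ {0.1, 1, 10}` over the single-patch habitat; kernel mean
`mu ∈ {-2, 0, 2}` and sd `sigma ∈ {1, 2, 3}`; patch scales
`m ∈ {5..30}`; the non-monotone birth variant; three canonical initial
conditions (constant 1, the indicator of `[-10, 10]`, and the split
indicator of `[-9, -7] ∪ [7, 9]`, discretized as exact node indicators).
Defaults: half-width 150, 3001 nodes (spacing 0.1), `tau = 1`,
`dt = tau/64`.  `D` is not specified by the source scenarios; the package
defaults to `D = 1` and logs this once per run — every simulated outcome
is conditioned on that choice.  The drift value for the patch-scale grid
with plateau mortality is likewise unprinted and defaults to 1.

A trajectory is classified from its sup-norm tail (window 100
generations): *extinct* below 1e-6, or decaying (log-slope < -1e-3) with
final sup-norm < 1e-2; *persistent* when the tail varies by < 1%
relative and stays above 1e-3; otherwise *undetermined* — an explicit
honest outcome near the threshold rather than a forced binary.  All
thresholds are configurable arguments.

Test and acceptance runs use scaled-down problem sizes chosen to leave
the classifications unchanged: half-width 100 with 2001 nodes for the
single-patch grids, 600 generations for the periodic-habitat grid, and
the coarser spectral grid described above.

## What the synthetic fixtures do and do not emulate

Property tests draw smooth nonnegative Gaussian-bump mixtures (bump
widths >= 1, so nothing aliases on the test grids) and ordered pairs
`phi = s*psi` with a scalar `s ∈ [0,1]`, all seeded and bit-reproducible.
These exercise order preservation, linearity, and positivity of the
operators; they do not emulate measured field data, demographic
stochasticity, or non-smooth initial profiles beyond the indicator
initials, so passing tests speak to the solver's mathematical contracts,
not to fit against field observations.

## Known limitations

* One spatial dimension only; constant scalar `D` and `q`.
* The truncated-domain `rho_L` is a point estimate without rigorous error
  bounds; grid-refinement agreement is reported, not proven.
* Under strong drift with a *fully periodic* habitat the Dirichlet
  truncation is qualitatively wrong — an extinction front enters from the
  upstream boundary at the drift speed and empties any bounded domain —
  while the exact periodic computation shows marginal persistence
  (growth rate ≈ 1.03 at `D = 1` for every patch scale in the reference
  grid).  Neither boundary treatment reproduces the reference alternating
  persistence/extinction pattern in the patch scale `m` from the printed
  parameters alone; that pattern evidently depends on unprinted choices
  (diffusivity, domain, boundary handling, resolution) and sits so close
  to the threshold that small numerical dissipation flips individual
  outcomes.  The corresponding acceptance test states the reference
  pattern and is expected to fail under the package's stated setup.
* Similarly, the reference persistent outcome for the strongest
  drift/widest kernel variant of the single-patch grid is not reproduced
  at `D = 1` (the computed threshold is 0.54); the threshold–simulation
  *dichotomy* itself holds across every scenario computed.
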