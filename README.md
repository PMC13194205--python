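# streampop

Threshold dynamics for a stage-structured population in a heterogeneous
1-D habitat, modeled as a **hybrid system**: a within-season
reaction–advection–diffusion equation for the aquatic larval stage coupled
to a between-season **non-local impulsive birth** map for the winged adult
stage.  The package is aimed at spatial ecologists and mathematical
biologists studying persistence of stream organisms (the "drift paradox"
setting): larvae diffuse and are carried downstream by the current, while
adults fly and deposit eggs around breeding areas.

## Model

Within season `n` the larval density `u_n(t, x)` obeys

    du/dt = d/dx ( D du/dx - q u ) + f(x, u),      0 < t <= tau,

with diffusivity `D`, drift speed `q` and density-dependent mortality
`f(x, u) = -alpha(x) u - u^2`.  At the season's end, adults emerge, fly
according to a dispersal kernel `K`, and deposit eggs:

    u_{n+1}(0, x) = integral K(x - y) g(y, u_n(tau, y)) dy,

with a birth function `g(x, u) = r(x) u / (1 + u)` (Beverton–Holt) or the
non-monotone `g(x, u) = r(x) u (1 - u)`.  Writing `Phi_tau` for the season
solution operator, the dynamics reduce to iterating the **generation map**

    Q[u] = K * g(., Phi_tau[u]).

Habitat heterogeneity enters through piecewise-linear profiles: a
bounded favorable core (mortality floor `alpha = 0` on `[-m, m]`,
fecundity peak `r = 2` on `[-l, l]`) surrounded by unfavorable habitat —
a BB-type configuration — or periodically repeating favorable patches.

**Persistence threshold.**  Linearizing `Q` at extinction gives the
positive operator `L[phi] = K * (eta(.) * P_tau[phi])` with
`eta = d_u g(., 0)`, `theta = d_u f(., 0)`, and `P_tau` the linear season
propagator.  The *asymptotic spectral radius*

    rho_L = lim_{rho -> inf}  rho( L restricted to the ball B_rho
                                   with the tent cutoff zeta_rho )

is the threshold: `rho_L > 1` implies a unique globally attractive
positive steady state; `rho_L < 1` implies extinction.  The package
estimates `rho_L` by sweeping truncation radii on a grid (dense
eigensolves or matrix-free power iteration) until the radii plateau.

## Worked example

```python
import numpy as np
import streampop as sp

# a single favorable patch (survival core m=5, breeding core l=10)
sc = sp.build_scenario("fig1", q=0.1, half_width=100.0, n_nodes=2001)
rho = sp.scenario_rho_L(sc)

traj = sc.run()
report = sp.classify_outcome(traj)
print(f"rho_L = {rho:.4f}")
print(f"outcome: {report.classification}, "
      f"steady-state sup-norm {report.final_sup_norm:.4f}")
```

prints

```
rho_L = 1.8030
outcome: persistent, steady-state sup-norm 0.4713
```

The threshold sits well above 1, and the simulated population indeed
settles on a positive steady state with peak density ~0.47 over the
favorable patch, decaying to zero away from it.  Raising the drift to
`q=10` pushes `rho_L` to ~4e-4 and the same simulation collapses to zero:
the current washes larvae off the patch faster than births replace them.

The `examples/` directory holds one short script per capability (season
solver vs. closed form, generation map arithmetic, threshold oracle,
scenario sweeps, periodic habitats); each prints the numbers it computes
and one line on what they mean.  A thin CLI mirrors the library:
`streampop simulate|rho|sweep|classify|fixtures`.

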