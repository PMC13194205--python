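"""Periodic habitats and strong drift: why the boundary treatment matters.

With both habitat profiles periodic and a constant initial condition, the
infinite-line solution is itself spatially periodic, and a circular domain
spanning the habitat period computes it exactly.  A zero-Dirichlet
truncation, by contrast, lets the drift (q = 15 per season) sweep an
extinction front in from the upstream boundary, emptying any bounded
domain regardless of habitat quality.
"""

import numpy as np

import streampop as sp

m = 10.0

# exact periodic computation on the commensurate circular domain
sc_per = sp.fig5_periodic_scenario(m, n_gens=300)
lin = sp.LinearizedModel.from_model(sc_per.model)
sgrid = sp.spectral_grid_for(sc_per.grid)
rho_per = sp.periodic_spectral_radius(lin, sgrid)
traj = sc_per.run()
print(f"periodic domain (width {2 * sc_per.grid.half_width:g}): "
      f"growth rate {rho_per:.4f}, sup-norm after 300 generations "
      f"{traj.sup_norms[-1]:.4g}")

# the same habitat under Dirichlet truncation
sc_dir = sp.build_scenario("fig5", m=m, n_gens=300)
rho_dir = sp.scenario_rho_L(sc_dir)
traj_d = sc_dir.run()
print(f"Dirichlet truncation (half-width {sc_dir.grid.half_width:g}): "
      f"rho_L {rho_dir:.3g}, sup-norm after 300 generations "
      f"{traj_d.sup_norms[-1]:.4g}")

print()
print("The periodic computation shows marginal persistence (growth rate "
      "slightly above 1); the truncated domain washes out at the drift "
      "speed.  For periodic habitats the BB-type decay assumption behind "
      "the truncation fails, so the circular domain is the faithful "
      "discretization.")
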