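"""Simulate the interacting particle system next to its mean-field PDE.

N particles attract each other through the mollified Riesz kernel
(drift (kappa/N) sum_j grad V^eta(X_i - X_j)) while diffusing; the
intermediate nonlocal equation evolves the same initial density with the same
kernel.  The cloud-in-cell histogram of the particles tracks the PDE density.
"""

import numpy as np

from modfluct import (
    RieszSpec, MollifierSpec, SimulationConfig, build_kernel_tables,
    simulate_interacting, deposit_particles, norms, GridField,
)
from modfluct.fluctstats import solve_intermediate_pde

config = SimulationConfig(N=512, d=3, lam=0.5, kappa=1, sigma=1.0,
                          beta=0.05, dt=0.01, T=0.5, seed=7)
print(f"moderate coupling: eta = N^-beta = {config.eta_value:.3f}")

spec = RieszSpec(config.d, config.lam)
grid = config.make_grid()
tables = build_kernel_tables(spec, MollifierSpec.from_particle_count(config.N, config.beta), grid)

ubar = solve_intermediate_pde(config, tables)
times, snaps = simulate_interacting(config, tables, config.rng(0))

for t, X in zip(times, snaps):
    dep = deposit_particles(X, grid, "CIC")
    l1 = norms(GridField(dep.values - ubar.field_at(float(t)).values, grid))["l1"]
    print(f"t = {t:.1f}:  L1(particle histogram, ubar) = {l1:.3f}")
# The L1 distance stays at the histogram-noise level (it creeps up slightly
# as diffusion spreads the cloud over more cells); there is no systematic
# drift away from the PDE because the particles follow the same dynamics in
# the mean.
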