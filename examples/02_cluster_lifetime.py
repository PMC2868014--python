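"""Cluster dissipation under the nominal EGFR reaction-diffusion model.

Nine receptors (150 receptors/um^2 over the 240 nm box) start as monomers at
random sites of the 48 nm high-density domain.  Within ~10 ms each monomer
either dimerizes or escapes over the barrier; dimers are then kinetically
trapped (their barrier hop rate is six orders of magnitude below their
in-domain diffusion) and the cluster dissipates over tens of seconds via
dimer dissociation followed by monomer escape, or direct dimer barrier hops.
"""

import numpy as np

from corralmc import simulate
from corralmc.metrics import cluster_lifetime, density_series, initial_cluster_density
from corralmc.scenarios import reaction_diffusion_scenario

scen = reaction_diffusion_scenario(density_um2=150.0, t_end=200.0)
geom = scen.build_geometry()

lifetimes, initial_densities = [], []
for rep in range(8):
    traj = simulate(scen, engine="acgmc", base_seed=42, replicate=rep, stop_below_ratio=5.0)
    (series,) = density_series(traj.frame, geom.n_central, geom.n_sites)
    life, censored = cluster_lifetime(series)
    icd = initial_cluster_density(series)
    lifetimes.append(life)
    initial_densities.append(icd)
    print(
        f"replicate {rep}: initial cluster density {icd:5.1f}, "
        f"lifetime {life:6.1f} s{' (censored)' if censored else ''}"
    )

print()
print(f"median initial cluster density: {np.median(initial_densities):.1f}")
print(f"median cluster lifetime:        {np.median(lifetimes):.1f} s")
print()
print(
    "The density ratio starts at 25 (all receptors in 4% of the area); the\n"
    "initial cluster density is the ratio at 0.1 s and the lifetime is the\n"
    "first sustained drop below 5.  Medians around 10-30 s show the cluster\n"
    "is held for seconds, not minutes, without any stabilizing mechanism."
)
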