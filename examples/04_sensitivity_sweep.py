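"""A small sensitivity sweep of the cluster lifetime.

Around the high-density case (833 receptors/um^2, 48 nm domain, dimer
barrier hopping disabled) the dissociation rate k_M and the dimerization
rate k_D pull the median cluster lifetime in opposite directions.  This is a
reduced version (2 replicates, shortened horizons) of the full sweep grids in
corralmc.scenarios; expect a few minutes of runtime.
"""

from corralmc.metrics import sweep

conditions = [
    {"name": "nominal", "density_um2": 833.0, "domain_side_nm": 48.0,
     "dimer_barrier": False, "multipliers": {}, "t_end": 100.0},
    {"name": "kM_x10", "density_um2": 833.0, "domain_side_nm": 48.0,
     "dimer_barrier": False, "multipliers": {"k_m": 10.0}, "t_end": 30.0},
    {"name": "kD_x10", "density_um2": 833.0, "domain_side_nm": 48.0,
     "dimer_barrier": False, "multipliers": {"k_d": 10.0}, "t_end": 100.0},
]

records, summary = sweep(conditions, n_replicates=2, base_seed=17)
print(summary[["condition", "median_lifetime_s", "n_censored"]].to_string(index=False))
print()
print(
    "Raising k_M x10 dissolves the cluster roughly an order of magnitude\n"
    "faster (more time spent in the mobile monomer form); raising k_D x10\n"
    "locks receptors into dimers and extends the lifetime several-fold.\n"
    "Lifetimes censored at t_end are reported at that lower bound."
)
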