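"""Compare the three engines on the pure-diffusion benchmark.

64 receptors start packed in the 48 nm high-density domain (fully covered)
and leak out over the diffusion barrier.  Exact KMC, uniform coarse-grained
MC (which replaces the barrier with the two-time-scale effective rate) and
adaptive coarse-grained MC should produce statistically identical
central-region density curves — coarse-graining pure diffusion is exact in
the mean.
"""

import numpy as np

from corralmc import diffusion_only_scenario, simulate

scen = diffusion_only_scenario(t_end=0.1, n_samples=10)
n_rep = 8

print("time_s      kmc    ucgmc    acgmc   (mean central receptors)")
curves = {}
for engine in ("kmc", "ucgmc", "acgmc"):
    reps = []
    for rep in range(n_rep):
        traj = simulate(scen, engine=engine, base_seed=5, replicate=rep)
        frame = traj.frame
        reps.append(
            frame[frame.region == "central"].sort_values("time_s")["n_receptors"].to_numpy()
        )
    curves[engine] = np.mean(reps, axis=0)

times = sorted(scen.sample_times)
for i, t in enumerate(times):
    print(
        f"{t:8.4f} {curves['kmc'][i]:8.1f} {curves['ucgmc'][i]:8.1f} {curves['acgmc'][i]:8.1f}"
    )

print()
print(
    "All three columns should agree to within Monte-Carlo noise: the domain\n"
    "drains from 64 receptors toward the equidistributed ~2.6 (= 64 sites /\n"
    "1600 sites * 64 receptors) on a ~10 ms time scale set by the barrier."
)
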