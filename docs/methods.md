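# Methods

`corralmc` simulates the diffusion, reversible dimerization and cluster
dissipation of membrane receptors (the EGFR system is the motivating case) on
a periodic square lattice containing a high-density microdomain (a raft,
clathrin pit or corral interior) separated from the surrounding low-density
membrane by a diffusion barrier.  Three engines share one stochastic
formalism and one compiled event loop; they differ only in how space is
resolved.

## Microscopic model

The membrane patch is an `n x n` lattice of spacing `a = 6 nm` with periodic
boundaries.  Each site is typed CENTRAL (inside the high-density domain) or
OUTER, holds at most one occupant — a monomer M or a dimer D (a dimer sits on
one site and counts as two receptors) — and the receptor number
`N_M + 2 N_D` is conserved exactly.  Four-neighbor (von Neumann)
connectivity is used; it is the convention of the lattice-KMC lineage this
model belongs to and keeps the per-site channel count minimal.

Event channels and propensities:

* **Hop** `X + * -> * + X` for X in {M, D}, one channel per (occupied site,
  vacant neighbor): rate Γ depends on the species and on the pair of site
  types.  A channel whose two sites have different types is a *barrier*
  channel regardless of direction.  Nominal values (s^-1): monomer in-domain
  2.50e5, monomer barrier 2.50e2, dimer in-domain 1.25e5, dimer barrier
  1.25e-1.  The dimer barrier can be switched off entirely (its propensity is
  then exactly 0), mimicking dimers that effectively cannot leave the domain.
* **Dimerization** `M + M -> D + *`, one channel per unordered adjacent
  monomer pair at `k_D = 5.67e2 s^-1`; the product dimer is placed on one of
  the two parent sites by a fair coin flip (symmetric, no drift).
* **Monomerization** `D + * -> M + M`, one channel per (dimer, vacant
  neighbor) at `k_M = 1.70e-2 s^-1` each, so a dimer's total dissociation
  propensity scales with its free volume (4 k_M when fully uncaged, 0 when
  caged).  The alternative convention — a total of k_M split across
  vacancies — was considered and rejected: under the per-channel convention
  the two dissipation mechanisms (dissociation-then-escape vs direct dimer
  barrier hops) contribute at the same order with dissociation slightly
  dominant, which is the observed mechanism balance of this parameter set,
  and the simulated dissipation window matches expectation.  The choice is
  isolated in one place (`kinetics` and the coarse expectation forms) if a
  user wants the other convention via a rate multiplier.

Exact simulation follows the Gillespie prescription on the lattice: waiting
time `tau = ln(1/u) / a_0` with `a_0` the propensity sum, event selection
proportional to propensity through a binary sum tree (O(log n) select and
update), incremental propensity updates restricted to channels touching the
one or two modified sites, and a full tree rebuild every 1e6 events to bound
floating-point drift (root-vs-leaf-sum agreement is tested to 1e-9
relative).  A state with `a_0 = 0` is absorbing: remaining samples are
frozen and flagged, not raised as an error.

## Coarse graining

Coarse cells group sites (8 x 8 in the standard layouts) and carry particle
counts per species; positions inside a cell are deliberately not represented.
Every coarse propensity is defined as the **exact expectation of the summed
microscopic propensities under uniform random placement** of the cell's
particles on its sites (hypergeometric forms within a cell, independent
marginals across cells):

* within-cell dimerization: `k_D E n_M (n_M - 1) / (q (q - 1))` with `E`
  internal bonds and `q` sites;
* within-cell dissociation: `k_M 2E n_D (q - n) / (q (q - 1))` with `n`
  occupied sites;
* cross-cell forms per shared boundary bond: `k_D l (n_M_a/q_a)(n_M_b/q_b)`
  and `k_M l (n_D_a/q_a)(1 - n_b/q_b)`.

These closed forms are verified against brute-force placement enumeration in
exact rational arithmetic for every cell shape up to 3 x 3 and every
admissible particle content.  For `q = 1` everything reduces to the
microscopic propensities, and the test suite checks the resulting channel set
is *identical* (kinds, site pairs and rates) to an independent site-based
enumeration — the refinement identity that makes "KMC" the all-fine special
case of one engine.

The well-mixed assumption is exactly what makes uniform coarse graining err
for bimolecular reactions in the crowded domain; reproducing that error with
the uniform mesh, and removing it with the adaptive mesh (fine cells exactly
where the CENTRAL sites are), is intended behavior.  The adaptive mesh
refines any coarse tile containing CENTRAL sites, so every coarse cell is
single-type; mixed-type coarse cells are rejected as configuration errors
(none of the standard layouts need them).  The mesh is static: "adaptive"
refers to spatial adaptation to the domain layout, not on-the-fly remeshing.

### Coarse diffusion and the barrier

Hops between cells use a conductance per boundary bond column obtained by
composing resistances in series — half the span of in-cell hops on each side
plus the crossing bond:

    g = [ (L_a - 1)/(2 Γ_a) + 1/Γ_cross + (L_b - 1)/(2 Γ_b) ]^-1

and the pair propensity is `g_total (N_a / q_a)(1 - N_b / q_b)` summed over
the shared edge.  This one formula reproduces: the microscopic rate for
fine-fine bonds (spans 1), the Fickian coarse-mesh diffusivity `D = Γ a^2`
for equal cells (single-particle MSD on the coarse mesh matches the fine
walk), the two-time-scale **effective barrier rate**

    Γ_eff = L_CG / ( (L_CG - 1)/Γ_micro + 1/Γ_barrier )

for equal coarse cells separated by a barrier (equal to `Γ_micro` when the
barrier vanishes, `~ L_CG Γ_barrier` when the barrier dominates, monotone in
both rates, zero for a blocked barrier), and the fine-coarse interface rule
in which the fine side contributes no coarse resistance.  The composition is
validated dynamically: the mean central-density decay curves of the three
engines for pure diffusion coincide within Monte-Carlo error, and a closed
fine+coarse system relaxes to uniform per-site occupancy.

Incoming interface channels target a specific vacant fine boundary site
(channel per bond), keeping propensities exact and the channel table static.

## Scenarios

* **Diffusion-only**: 240 nm box, 48 nm domain fully covered by 64 copies of
  a single mobile species, in-domain hops 2.5e5 /s, barrier 2.5e2 /s, no
  reactions.  Used to validate coarse diffusion.
* **Reaction-diffusion**: overall receptor density ρ (nominal 150 /um^2,
  high-density variant 833 /um^2) over the box; the realized count is
  `round(ρ x box area)` (9 and 48 receptors respectively — logged in run
  metadata since the nominal densities are round numbers), all placed as
  monomers at random distinct CENTRAL sites: the worst case for cluster
  lifetime.  Per-site occupancy at nominal density is ρ a^2 ≈ 0.0054 < 0.01,
  the dilute regime in which the outer region is effectively well mixed.

Replicate seeds derive from a base seed through `numpy` `SeedSequence`
children (one per replicate, split into a placement stream and an event-loop
stream), so runs are bit-reproducible and replicates are independent.
Sample schedules are log-spaced by default (the dynamics span ~1 ms to
~200 s); each sample reports the state immediately before the first event
after the sample time.

## Metrics

The clustering observable is `ratio(t) = ρ_HDR(t) / ρ_overall`
(receptor-weighted central density over the conserved overall density; 25 at
a fully loaded 4% domain, 1 at equidistribution).  Two scalars per
trajectory:

* **initial cluster density**: the ratio at the sample nearest 0.1 s (ties to
  the earlier sample) — by then the initial monomers have dimerized or left;
* **cluster lifetime**: the first sample strictly below ratio 5 followed by
  two further samples below (a 3-sample de-bounce, because small-count
  trajectories chatter near the threshold; the threshold itself is part of
  the model definition, the de-bounce is a numerical choice).  Lifetimes not
  reached by the end of a run are censored and reported at the horizon as a
  lower bound; condition summaries use medians with IQR and are marked
  indeterminate if more than half the replicates are censored.

Sweeps run condition grids (domain size x density x dimer-barrier switch;
rate multipliers x2/x10 on k_M, k_D and the monomer barrier rate around the
833 /um^2, barrier-off case) with per-condition derived seeds so conditions
can be added without perturbing one another.  Runs that only need the
lifetime may stop early once the ratio has stayed below threshold for the
de-bounce window; the metric is unchanged by construction.

## Problem sizes and numerical choices

Replicate counts are sized so each check is statistically decisive for its
assertion: 32 replicates for the dissipation-window median (about ±2 s
standard error on a ~14 s median), 24 per engine for the three-way diffusion
comparison (3-combined-standard-error bands at every sample), 48 for the
headline median recomputed by `scripts/acceptance.py`, and 3 per condition
for the sensitivity orderings, whose effect sizes (roughly 10x down for
k_M x10, 2-3x up for k_D x10, 2-3x down for enabling the dimer barrier) dwarf
replicate scatter.  Sweep horizons are capped per condition (40-120 s)
with early stopping at the crossing.  The stationarity oracle runs 1e6
events on the 3 x 3 two-receptor sector with order-unity rates chosen so
hopping and both reactions mix on comparable scales (the nominal constants
span nine orders of magnitude and would not equilibrate the slow reaction
sector in any affordable event budget; the oracle tests the engine, not the
biology).

## Limitations

* No energetic receptor-receptor interactions and no explicit ligand
  binding: clustering here is purely kinetic trapping by barriers.
* Two site types, rectangular domains, static meshes; no error-estimator
  driven refinement.
* The synthetic scenarios emulate idealized membrane microdomains: square
  corrals, a single barrier rate per species, spatially uniform rates.
  Passing tests demonstrate correctness of the stochastic numerics and
  internal consistency of the coarse-graining, not that real membranes have
  these rate constants.
* Wall-clock instrumentation (event totals, run times in metadata) is
  provided for orientation, but relative engine costs are
  hardware-dependent and are not validated quantities.
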