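"""Waiting times, binary-tree selection, reproducibility, engine behavior."""

import math

import numpy as np
import pytest

from corralmc import (
    EventTree,
    MicroState,
    Species,
    build_geometry,
    run_reference,
    simulate,
    waiting_time,
)
from corralmc.engine import select_channel
from corralmc.kinetics import RateTable, HOP
from corralmc.scenarios import Scenario, diffusion_only_scenario, log_sample_times


def test_waiting_time_closed_forms():
    assert waiting_time(1.0, 0.5) == pytest.approx(math.log(2.0))
    assert waiting_time(2.0, math.exp(-2.0)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        waiting_time(0.0, 0.5)


def test_waiting_time_is_exponential(rng):
    a0 = 4.0
    draws = np.array([waiting_time(a0, 1.0 - rng.random()) for _ in range(100_000)])
    se = draws.std() / math.sqrt(draws.size)
    assert abs(draws.mean() - 0.25) < 3 * se


def test_tree_selection_cumulative_intervals():
    tree = EventTree([1.0, 3.0])
    assert select_channel(tree, 0.5) == 0
    assert select_channel(tree, 2.0) == 1
    with pytest.raises(ValueError):
        select_channel(tree, 4.0)
    single = EventTree([2.5])
    assert select_channel(single, 1.0) == 0


def test_tree_selection_frequencies(rng):
    from scipy.stats import chisquare

    p = np.array([1.0, 2.0, 3.0, 4.0])
    tree = EventTree(p)
    counts = np.zeros(4)
    n = 100_000
    for r in rng.random(n) * tree.total:
        counts[tree.select(r)] += 1
    _, pval = chisquare(counts, n * p / p.sum())
    assert pval > 0.001


def test_tree_update_keeps_root_consistent(rng):
    p = rng.random(37)
    tree = EventTree(p)
    for _ in range(2000):
        i = rng.integers(0, 37)
        p[i] = rng.random()
        tree.update(int(i), p[i])
    assert tree.total == pytest.approx(p.sum(), rel=1e-9)


def _tiny_scenario():
    return Scenario(
        box_nm=48.0,
        lattice_nm=6.0,
        domains=[{"x_nm": 12.0, "y_nm": 12.0, "side_nm": 24.0}],
        rates=RateTable(),
        density_um2=None,
        placement="full_cover",
        sample_times=log_sample_times(1e-5, 1e-2, 10),
    )


@pytest.mark.parametrize("engine", ["kmc", "acgmc"])
def test_identical_seed_gives_identical_trajectory(engine):
    scen = _tiny_scenario()
    a = simulate(scen, engine=engine, base_seed=42, replicate=0)
    b = simulate(scen, engine=engine, base_seed=42, replicate=0)
    assert a.frame.equals(b.frame)
    assert a.meta["n_events"] == b.meta["n_events"]
    c = simulate(scen, engine=engine, base_seed=43, replicate=0)
    assert not a.frame.equals(c.frame)


def test_receptor_conservation_at_every_sample():
    scen = _tiny_scenario()
    traj = simulate(scen, engine="kmc", base_seed=1)
    totals = traj.frame.groupby("time_s")["n_receptors"].sum().to_numpy()
    assert np.all(totals == traj.meta["n_receptors"])


def test_empty_lattice_is_absorbing():
    scen = Scenario(
        box_nm=24.0,
        lattice_nm=6.0,
        domains=[],
        rates=RateTable(),
        placement="full_cover",
        sample_times=log_sample_times(1e-3, 1.0, 5),
    )
    traj = simulate(scen, engine="kmc", base_seed=0)
    assert traj.meta["absorbing"]
    assert traj.meta["n_events"] == 0
    assert (traj.frame["n_receptors"] == 0).all()


def test_single_dimer_first_event_is_exponential(rng):
    """k_D = Gamma = 0 and one dimer: the first-event time is Exponential
    with rate 4 k_M (one dissociation channel per vacant neighbor)."""
    geom = build_geometry(30.0, 6.0, [])
    rates = RateTable(
        gamma_m_central=0.0,
        gamma_m_outer=0.0,
        gamma_d_central=0.0,
        gamma_d_outer=0.0,
        gamma_m_barrier=0.0,
        gamma_d_barrier=0.0,
        k_d=0.0,
        k_m=2.0,
    )
    times = []
    for _ in range(4000):
        state = MicroState.empty(geom)
        state.occ[2, 2] = Species.DIMER
        run_reference(state, rates, t_end=np.inf, rng=rng, max_events=1)
        times.append(state.t)
    times = np.array(times)
    expected = 1.0 / (4 * 2.0)
    se = times.std() / math.sqrt(times.size)
    assert abs(times.mean() - expected) < 3 * se


def test_reference_engine_msd_matches_random_walk_law(rng):
    """Single-particle mean-square displacement = 4 Gamma a^2 t (a = 1 site)."""
    geom = build_geometry(90.0, 6.0, [])  # 15x15, homogeneous
    gamma = 1.0
    rates = RateTable(
        gamma_m_central=gamma,
        gamma_m_outer=gamma,
        gamma_m_barrier=gamma,
        k_d=0.0,
        k_m=0.0,
    )
    t_end = 50.0
    sq_disps = []
    for _ in range(120):
        state = MicroState.empty(geom)
        state.occ[7, 7] = Species.MONOMER
        disp = np.zeros(2)

        def on_event(t, ch, disp=disp):
            (r1, c1), (r2, c2) = ch.sites
            dr = (r2 - r1 + 7) % 15 - 7
            dc = (c2 - c1 + 7) % 15 - 7
            disp += (dr, dc)

        run_reference(state, rates, t_end=t_end, rng=rng, on_event=on_event)
        sq_disps.append(disp @ disp)
    sq_disps = np.array(sq_disps, dtype=float)
    expected = 4 * gamma * t_end  # site units
    se = sq_disps.std() / math.sqrt(sq_disps.size)
    assert abs(sq_disps.mean() - expected) < 3 * se


def test_fast_engine_matches_reference_on_small_reaction_system():
    """Dual-route check: compiled kernel vs direct-method reference engine.

    Mean monomer count at a fixed time on a small homogeneous lattice with
    reversible dimerization must agree within 3 combined standard errors.
    """
    geom = build_geometry(36.0, 6.0, [])  # 6x6
    rates = RateTable(
        gamma_m_central=5.0,
        gamma_m_outer=5.0,
        gamma_m_barrier=5.0,
        gamma_d_central=2.0,
        gamma_d_outer=2.0,
        gamma_d_barrier=2.0,
        k_d=3.0,
        k_m=2.0,
    )
    t_obs = 2.0
    n_rep = 200

    def init(geom, rng):
        state = MicroState.empty(geom)
        for s in rng.choice(36, size=8, replace=False):
            state.occ[s // 6, s % 6] = Species.MONOMER
        return state

    ref_counts = []
    rng = np.random.default_rng(77)
    for _ in range(n_rep):
        state = init(geom, rng)
        samples = run_reference(state, rates, t_end=t_obs, rng=rng, sample_times=[t_obs])
        ref_counts.append(samples[0].counts()[0])

    fast_counts = []
    scen = _random_eight_scenario(rates, t_obs)
    for rep in range(n_rep):
        traj = simulate(scen, engine="kmc", base_seed=9, replicate=rep)
        frame = traj.frame
        row = frame[(frame.time_s == t_obs)]
        fast_counts.append(int(row["n_monomer"].sum()))

    ref = np.array(ref_counts, float)
    fast = np.array(fast_counts, float)
    se = math.sqrt(ref.var() / ref.size + fast.var() / fast.size)
    assert abs(ref.mean() - fast.mean()) <= 3 * se


def _random_eight_scenario(rates, t_obs):
    # 8 receptors on a 6x6 all-CENTRAL box, random placement
    return Scenario(
        box_nm=36.0,
        lattice_nm=6.0,
        domains=[{"x_nm": 0.0, "y_nm": 0.0, "side_nm": 36.0}],
        rates=rates,
        density_um2=8 / (0.036**2),
        placement="random_central",
        sample_times=[0.0, t_obs],
        cg_cell_sites=1,
    )
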