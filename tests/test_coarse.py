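"""Meshes, coarse propensities vs brute-force expectations, interface physics."""

import math
from fractions import Fraction

import numpy as np
import pytest

from corralmc import MicroState, Species, build_geometry, build_mesh, enumerate_channels
from corralmc.coarse import (
    ConfigurationError,
    bond_conductance,
    build_channel_table,
    coarse_count,
    counts_from_microstate,
    effective_barrier_rate,
    intra_dimerization_propensity,
    intra_monomerization_propensity,
    pair_dimerization_propensity,
    pair_monomerization_propensity,
)
from corralmc.kinetics import RateTable
from oracle_helpers import placement_expectation, pair_placement_expectation


def test_mesh_layout_cell_counts(nominal_geometry):
    fine = build_mesh(nominal_geometry, "fine")
    assert fine.n_cells == 1600
    assert np.all(fine.q == 1)
    uniform = build_mesh(nominal_geometry, "uniform", 8)
    assert uniform.n_cells == 25
    assert np.all(uniform.q == 64)
    adaptive = build_mesh(nominal_geometry, "adaptive", 8)
    assert adaptive.n_cells == 64 + 24
    assert np.count_nonzero(adaptive.q == 1) == 64
    assert np.count_nonzero(adaptive.q == 64) == 24


def test_adaptive_mesh_refines_any_tile_touching_the_domain():
    # 24 nm domain sits inside a single 8x8 tile: that tile is refined
    geom = build_geometry(240.0, 6.0, [((108.0, 108.0), 24.0)])
    mesh = build_mesh(geom, "adaptive", 8)
    assert mesh.n_cells == 64 + 24
    # every CENTRAL site is its own cell
    fine_types = mesh.cell_type[mesh.q == 1]
    assert np.count_nonzero(fine_types == 1) == 16


def test_uniform_mesh_rejects_mixed_tiles():
    geom = build_geometry(240.0, 6.0, [((108.0, 108.0), 24.0)])
    with pytest.raises(ConfigurationError):
        build_mesh(geom, "uniform", 8)
    with pytest.raises(ConfigurationError):
        build_mesh(geom, "uniform", 7)  # indivisible tiling


def test_mesh_partitions_sites(nominal_geometry):
    for kind in ("fine", "uniform", "adaptive"):
        mesh = build_mesh(nominal_geometry, kind, 8)
        sizes = np.bincount(mesh.cell_of.reshape(-1), minlength=mesh.n_cells)
        assert np.array_equal(sizes, mesh.q)


def test_coarse_count_equals_microscopic_sum(nominal_geometry, rng):
    mesh = build_mesh(nominal_geometry, "uniform", 8)
    state = MicroState.empty(nominal_geometry)
    for s in rng.choice(1600, size=100, replace=False):
        state.occ[s // 40, s % 40] = rng.choice([1, 2])
    state.clear_cache()
    nm, nd = counts_from_microstate(mesh, state)
    assert nm.sum() == state.counts()[0]
    assert nd.sum() == state.counts()[1]
    k = int(mesh.cell_of[0, 0])
    sites = mesh.cell_sites(k)
    manual = sum(1 for r, c in sites if state.occ[r, c] == Species.MONOMER)
    assert coarse_count(mesh, state, k, Species.MONOMER) == manual


@pytest.mark.parametrize("w,h", [(1, 2), (2, 2), (3, 2), (3, 3)])
def test_intra_cell_propensities_match_placement_enumeration(w, h):
    """Closed-form coarse reaction propensities equal exhaustive-placement
    expectations for every admissible particle content (exact rationals)."""
    q = w * h
    E = w * (h - 1) + h * (w - 1)
    k_m, k_d = Fraction(17, 1000), Fraction(567)
    for n_d in range(q + 1):
        for n_m in range(q - n_d + 1):
            mono_oracle, dim_oracle = placement_expectation(
                w, h, n_m, n_d, k_m, k_d
            )
            mono = intra_monomerization_propensity(q, E, n_m, n_d, float(k_m))
            dim = intra_dimerization_propensity(q, E, n_m, float(k_d))
            assert math.isclose(mono, float(mono_oracle), rel_tol=1e-12, abs_tol=1e-15)
            assert math.isclose(dim, float(dim_oracle), rel_tol=1e-12, abs_tol=1e-15)


def test_intra_cell_examples():
    # 2x2 cell, one dimer alone: 4 internal edges, average vacant-neighbor
    # count per placement is 2, so total = k_m * 2
    assert intra_monomerization_propensity(4, 4, 0, 1, 1.0) == pytest.approx(2.0)
    # 2x2 cell, two monomers: 4 of 6 placements adjacent -> k_d * 2/3
    assert intra_dimerization_propensity(4, 4, 2, 1.0) == pytest.approx(2.0 / 3.0)
    # full cell: deterministic placement, all internal edges are M-M pairs
    assert intra_dimerization_propensity(4, 4, 4, 1.0) == pytest.approx(4.0)
    assert intra_dimerization_propensity(1, 0, 1, 1.0) == 0.0
    assert intra_monomerization_propensity(9, 12, 0, 0, 1.0) == 0.0


def test_pair_propensities_match_independent_placement(rng):
    for _ in range(20):
        w, h = rng.integers(1, 4), rng.integers(1, 4)
        q = w * h
        ell = int(rng.integers(1, h + 1))
        n_m_a, n_d_a = rng.integers(0, q + 1), 0
        n_d_a = int(rng.integers(0, q - n_m_a + 1))
        n_m_b = int(rng.integers(0, q + 1))
        n_d_b = int(rng.integers(0, q - n_m_b + 1))
        o_ab, o_ba, o_dim = pair_placement_expectation(
            w, h, n_m_a, n_d_a, n_m_b, n_d_b, ell, Fraction(3, 7), Fraction(5, 3)
        )
        assert math.isclose(
            pair_monomerization_propensity(ell, q, n_d_a, q, n_m_b + n_d_b, 3 / 7),
            float(o_ab),
            rel_tol=1e-12,
            abs_tol=1e-15,
        )
        assert math.isclose(
            pair_monomerization_propensity(ell, q, n_d_b, q, n_m_a + n_d_a, 3 / 7),
            float(o_ba),
            rel_tol=1e-12,
            abs_tol=1e-15,
        )
        assert math.isclose(
            pair_dimerization_propensity(ell, q, n_m_a, q, n_m_b, 5 / 3),
            float(o_dim),
            rel_tol=1e-12,
            abs_tol=1e-15,
        )


def test_effective_barrier_rate_limits():
    gm, gb = 2.5e5, 2.5e2
    # no barrier: reduces to the in-domain microscopic rate
    assert effective_barrier_rate(gm, gm, 8) == pytest.approx(gm)
    # blocked barrier
    assert effective_barrier_rate(gm, 0.0, 8) == 0.0
    # barrier-limited: ~ L * Gamma_barrier
    val = effective_barrier_rate(gm, gb, 8)
    assert val == pytest.approx(8.0 / (7.0 / gm + 1.0 / gb))
    assert val < 8 * gb
    # monotone in both arguments
    assert effective_barrier_rate(2 * gm, gb, 8) >= val
    assert effective_barrier_rate(gm, 2 * gb, 8) >= val


def test_bond_conductance_limits():
    # fine-fine reduces exactly to the crossing rate
    assert bond_conductance(1, 123.0, 1, 456.0, 789.0) == 789.0
    # equal coarse cells with a barrier: effective rate / span
    g = bond_conductance(8, 2.5e5, 8, 2.5e5, 2.5e2)
    assert g == pytest.approx(effective_barrier_rate(2.5e5, 2.5e2, 8) / 8.0)
    # no-barrier fine-coarse interface: Fickian 2 Gamma / (L + 1)
    g = bond_conductance(1, 100.0, 9, 100.0, 100.0)
    assert g == pytest.approx(2 * 100.0 / 10.0)


def test_fine_mesh_channel_table_reproduces_microscopic_channels(
    nominal_geometry, nominal_rates, rng
):
    """Refinement identity: the all-q=1 channel table expands to exactly the
    microscopic channel set of the independent enumeration."""
    state = MicroState.empty(nominal_geometry)
    for s in rng.choice(1600, size=150, replace=False):
        state.occ[s // 40, s % 40] = rng.choice([1, 2], p=[0.6, 0.4])
    state.clear_cache()
    mesh = build_mesh(nominal_geometry, "fine")
    table = build_channel_table(nominal_geometry, mesh, nominal_rates)
    nm, nd = counts_from_microstate(mesh, state)

    n = nominal_geometry.n_side
    expanded = []
    for c in range(len(table.ch_a)):
        a, b = int(table.ch_a[c]), int(table.ch_b[c])
        assert b >= 0  # no intra channels on a fine mesh
        sa, sb = (a // n, a % n), (b // n, b % n)
        ma, da = nm[a], nd[a]
        mb, db = nm[b], nd[b]
        va, vb = 1 - ma - da, 1 - mb - db
        for val, kind, pair in [
            (table.g_hop_m[c] * ma * vb, "HOP", (sa, sb)),
            (table.g_hop_m[c] * mb * va, "HOP", (sb, sa)),
            (table.g_hop_d[c] * da * vb, "HOP", (sa, sb)),
            (table.g_hop_d[c] * db * va, "HOP", (sb, sa)),
            (table.g_dim[c] * ma * mb, "DIMERIZE", tuple(sorted((sa, sb)))),
            (table.g_mono[c] * da * vb, "MONOMERIZE", (sa, sb)),
            (table.g_mono[c] * db * va, "MONOMERIZE", (sb, sa)),
        ]:
            if val > 0:
                expanded.append((kind, pair, val))

    micro = [
        (ch.kind, ch.sites if ch.kind != "DIMERIZE" else tuple(sorted(ch.sites)), ch.propensity)
        for ch in enumerate_channels(state, nominal_rates)
    ]
    assert sorted(expanded) == sorted(micro)


def test_interface_equilibrium_occupancy(rng):
    """Closed fine+coarse system relaxes to uniform per-site occupancy.

    One refined tile next to coarse tiles: at stationarity each of the
    lattice's sites must be equally likely to hold the single particle, i.e.
    the mean particle count in the fine region matches its site fraction.
    """
    from corralmc import simulate
    from corralmc.scenarios import Scenario

    rates = RateTable(
        gamma_m_central=1000.0,
        gamma_m_outer=1000.0,
        gamma_m_barrier=100.0,
        gamma_d_central=0.0,
        gamma_d_outer=0.0,
        gamma_d_barrier=0.0,
        k_d=0.0,
        k_m=0.0,
    )
    scen = Scenario(
        box_nm=96.0,
        lattice_nm=6.0,
        domains=[{"x_nm": 0.0, "y_nm": 0.0, "side_nm": 48.0}],
        rates=rates,
        placement="full_cover",
        sample_times=[0.0, 0.5, 1.0, 2.0],
        cg_cell_sites=8,
    )
    geom = scen.build_geometry()
    fracs = []
    for rep in range(60):
        traj = simulate(scen, engine="acgmc", base_seed=21, replicate=rep)
        last = traj.frame[traj.frame.time_s == 2.0]
        central = last[last.region == "central"]["n_receptors"].sum()
        fracs.append(central / traj.meta["n_receptors"])
    fracs = np.array(fracs)
    expected = geom.n_central / geom.n_sites
    se = fracs.std(ddof=1) / math.sqrt(fracs.size)
    assert abs(fracs.mean() - expected) <= 3 * max(se, 1e-6)
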