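"""Coarse cells, coarse propensities, and the mesh channel table.

Coarse-graining groups lattice sites into cells and evolves the per-cell
particle counts ``N_{species,k}`` instead of individual site occupancies.
Within a cell particles are treated as well mixed: every coarse propensity is
the *exact expectation* of the summed microscopic propensities over uniform
random placement of the cell's particles on its sites (without replacement).
For single-site cells (q = 1) everything reduces to the microscopic forms, so
a mesh of all q = 1 cells reproduces exact KMC channel by channel.

Three layouts are supported:

* ``fine``     — every site its own cell (exact KMC);
* ``uniform``  — the whole lattice tiled into ``L x L`` coarse cells (UCGMC);
* ``adaptive`` — tiles containing high-density (CENTRAL) sites are refined to
  single sites, all other tiles stay coarse (ACGMC).

Diffusion between cells separated by the domain barrier is a two-time-scale
process (fast in-cell hops, one slow barrier hop); the effective coarse rate
composes the two as resistances in series (:func:`effective_barrier_rate`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .lattice import ConfigurationError, Geometry, MicroState, Species, SiteType

__all__ = [
    "Mesh",
    "build_mesh",
    "ChannelTable",
    "build_channel_table",
    "counts_from_microstate",
    "coarse_count",
    "intra_monomerization_propensity",
    "intra_dimerization_propensity",
    "pair_dimerization_propensity",
    "pair_monomerization_propensity",
    "pair_hop_propensity",
    "effective_barrier_rate",
    "bond_conductance",
]


@dataclass
class Mesh:
    """Partition of the site set into cells.

    Arrays indexed by cell: ``q`` (sites per cell), ``cell_type`` (every cell
    is single-type by construction), ``span_r`` / ``span_c`` (cell extent in
    sites along rows / columns), ``internal_edges`` (adjacent site pairs with
    both ends in the cell).  ``cell_of`` maps each site to its cell.
    """

    kind: str
    cg_cell_sites: int
    cell_of: np.ndarray  # (n, n) int64
    q: np.ndarray
    cell_type: np.ndarray
    span_r: np.ndarray
    span_c: np.ndarray
    internal_edges: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.q.size)

    def cell_sites(self, k: int) -> np.ndarray:
        return np.argwhere(self.cell_of == k)

    def to_json(self) -> str:
        pairs = pair_adjacency(self)
        return json.dumps(
            {
                "kind": self.kind,
                "cg_cell_sites": self.cg_cell_sites,
                "n_cells": self.n_cells,
                "q": self.q.tolist(),
                "cell_type": self.cell_type.tolist(),
                "span_r": self.span_r.tolist(),
                "span_c": self.span_c.tolist(),
                "internal_edges": self.internal_edges.tolist(),
                "adjacency": [[int(a), int(b), int(l)] for (a, b), l in sorted(pairs.items())],
            }
        )


def build_mesh(geom: Geometry, kind: str, cg_cell_sites: int = 8) -> Mesh:
    """Build a ``fine`` / ``uniform`` / ``adaptive`` mesh over ``geom``."""
    n = geom.n_side
    st = geom.site_type
    if kind == "fine":
        cell_of = np.arange(n * n, dtype=np.int64).reshape(n, n)
        q = np.ones(n * n, dtype=np.int64)
        ctype = st.reshape(-1).astype(np.int64)
        ones = np.ones(n * n, dtype=np.int64)
        return Mesh(kind, 1, cell_of, q, ctype, ones.copy(), ones.copy(), np.zeros(n * n, dtype=np.int64))

    L = int(cg_cell_sites)
    if L < 1 or n % L != 0:
        raise ConfigurationError(
            f"coarse cell side {L} does not tile the {n}x{n} lattice"
        )
    n_tiles = n // L
    cell_of = np.empty((n, n), dtype=np.int64)
    q, ctype, span_r, span_c = [], [], [], []
    next_cell = 0
    for tr in range(n_tiles):
        for tc in range(n_tiles):
            block = st[tr * L : (tr + 1) * L, tc * L : (tc + 1) * L]
            has_central = bool(np.any(block == SiteType.CENTRAL))
            mixed = has_central and bool(np.any(block == SiteType.OUTER))
            if kind == "uniform":
                if mixed:
                    raise ConfigurationError(
                        "uniform mesh tile mixes CENTRAL and OUTER sites; "
                        "align the domain with the tiling or use the adaptive mesh"
                    )
                cell_of[tr * L : (tr + 1) * L, tc * L : (tc + 1) * L] = next_cell
                q.append(L * L)
                ctype.append(SiteType.CENTRAL if has_central else SiteType.OUTER)
                span_r.append(L)
                span_c.append(L)
                next_cell += 1
            elif kind == "adaptive":
                if has_central:  # refine the whole tile to single sites
                    for r in range(tr * L, (tr + 1) * L):
                        for c in range(tc * L, (tc + 1) * L):
                            cell_of[r, c] = next_cell
                            q.append(1)
                            ctype.append(int(st[r, c]))
                            span_r.append(1)
                            span_c.append(1)
                            next_cell += 1
                else:
                    cell_of[tr * L : (tr + 1) * L, tc * L : (tc + 1) * L] = next_cell
                    q.append(L * L)
                    ctype.append(SiteType.OUTER)
                    span_r.append(L)
                    span_c.append(L)
                    next_cell += 1
            else:
                raise ConfigurationError(f"unknown mesh kind {kind!r}")
    mesh = Mesh(
        kind,
        L,
        cell_of,
        np.array(q, dtype=np.int64),
        np.array(ctype, dtype=np.int64),
        np.array(span_r, dtype=np.int64),
        np.array(span_c, dtype=np.int64),
        np.zeros(len(q), dtype=np.int64),
    )
    _count_internal_edges(mesh)
    return mesh


def _iter_bonds(n: int):
    """Each undirected lattice bond once: (site_i, site_j, axis).

    axis 0 = vertical neighbor (row+1), axis 1 = horizontal (col+1); periodic.
    On width-2 lattices the wrap bond duplicates a pair — that is a genuine
    second bond and is kept.
    """
    for r in range(n):
        for c in range(n):
            yield (r, c), ((r + 1) % n, c), 0
            yield (r, c), (r, (c + 1) % n), 1


def _count_internal_edges(mesh: Mesh) -> None:
    n = mesh.cell_of.shape[0]
    E = np.zeros(mesh.n_cells, dtype=np.int64)
    for i, j, _ in _iter_bonds(n):
        a, b = mesh.cell_of[i], mesh.cell_of[j]
        if a == b:
            E[a] += 1
    mesh.internal_edges[:] = E


def pair_adjacency(mesh: Mesh) -> dict:
    """Shared-edge length (in bonds) per adjacent cell pair ``(a, b), a < b``."""
    n = mesh.cell_of.shape[0]
    pairs: dict = {}
    for i, j, _ in _iter_bonds(n):
        a, b = int(mesh.cell_of[i]), int(mesh.cell_of[j])
        if a != b:
            key = (min(a, b), max(a, b))
            pairs[key] = pairs.get(key, 0) + 1
    return pairs


# ---------------------------------------------------------------------------
# Coarse propensity closed forms (well-mixed expectations).
# ---------------------------------------------------------------------------


def intra_dimerization_propensity(q: int, internal_edges: int, n_m: int, k_d: float) -> float:
    """Dimerization propensity inside one cell.

    Expectation of ``k_d x (# adjacent M-M pairs)`` over uniform placement of
    the cell's particles: each of the ``E`` internal edges holds an M-M pair
    with probability ``n_m (n_m - 1) / (q (q - 1))``.
    """
    if q < 2 or n_m < 2:
        return 0.0
    return k_d * internal_edges * n_m * (n_m - 1) / (q * (q - 1))


def intra_monomerization_propensity(
    q: int, internal_edges: int, n_m: int, n_d: int, k_m: float
) -> float:
    """Dissociation propensity inside one cell.

    One microscopic channel per (dimer, vacant neighbor) ordered pair at rate
    ``k_m``; over uniform placement each of the ``2E`` ordered internal pairs
    carries probability ``n_d / q x (q - n) / (q - 1)`` with
    ``n = n_m + n_d`` occupied sites.
    """
    if q < 2 or n_d < 1:
        return 0.0
    vac = q - n_m - n_d
    return k_m * 2 * internal_edges * n_d * vac / (q * (q - 1))


def pair_dimerization_propensity(
    ell: int, q_a: int, n_m_a: int, q_b: int, n_m_b: int, k_d: float
) -> float:
    """Dimerization across the shared edge (``ell`` boundary bonds) of two cells."""
    return k_d * ell * n_m_a * n_m_b / (q_a * q_b)


def pair_monomerization_propensity(
    ell: int, q_a: int, n_d_a: int, q_b: int, n_occ_b: int, k_m: float
) -> float:
    """Dissociation of a dimer in cell a placing one monomer into cell b."""
    return k_m * ell * n_d_a * (q_b - n_occ_b) / (q_a * q_b)


def bond_conductance(
    span_a: int, gamma_a: float, span_b: int, gamma_b: float, gamma_cross: float
) -> float:
    """Effective per-bond hop rate between two cells, one boundary column.

    Series-resistance composition of half the span of in-cell hops on either
    side plus the single crossing bond: a cell of span ``L`` contributes
    ``(L - 1) / (2 Gamma)`` resistance (its boundary-to-center traverse), the
    crossing bond ``1 / Gamma_cross``.  Fine-fine bonds (both spans 1) reduce
    exactly to ``Gamma_cross``; equal coarse cells with a barrier recover the
    two-time-scale effective rate ``effective_barrier_rate(...) / L``.
    """
    if gamma_cross <= 0.0:
        return 0.0
    if span_a == 1 and span_b == 1:
        return gamma_cross
    res = 1.0 / gamma_cross
    if span_a > 1:
        if gamma_a <= 0.0:
            return 0.0
        res += (span_a - 1) / (2.0 * gamma_a)
    if span_b > 1:
        if gamma_b <= 0.0:
            return 0.0
        res += (span_b - 1) / (2.0 * gamma_b)
    return 1.0 / res


def effective_barrier_rate(gamma_micro: float, gamma_barrier: float, l_cg: int) -> float:
    """Effective diffusion rate between two coarse cells separated by a barrier.

    Crossing one coarse spacing means ``L_CG - 1`` fast microscopic hops plus
    one slow barrier hop; composing the mean times and rescaling to a single
    equivalent rate gives::

        Gamma_eff = L_CG / ( (L_CG - 1)/Gamma_micro + 1/Gamma_barrier )

    Monotone non-decreasing in both rates, equal to ``Gamma_micro`` in the
    single-time-scale limit (no barrier), and vanishing as the barrier closes.
    """
    if l_cg < 1:
        raise ValueError("l_cg must be >= 1")
    if gamma_barrier <= 0.0:
        return 0.0
    if gamma_micro <= 0.0:
        return 0.0
    return l_cg / ((l_cg - 1) / gamma_micro + 1.0 / gamma_barrier)


def pair_hop_propensity(
    g_sum: float, q_a: int, n_species_a: int, q_b: int, n_occ_b: int
) -> float:
    """Hop propensity cell a -> cell b given summed bond conductance ``g_sum``.

    ``g_sum x (N_a / q_a) x (1 - N_b / q_b)``: well-mixed origin occupancy and
    destination exclusion.
    """
    return g_sum * n_species_a * (q_b - n_occ_b) / (q_a * q_b)


# ---------------------------------------------------------------------------
# Channel table for the compiled kernel.
# ---------------------------------------------------------------------------


@dataclass
class ChannelTable:
    """Flat channel arrays consumed by the event-loop kernel.

    A channel is either a cell *pair* (``ch_b >= 0``) carrying hop,
    cross-dimerization and cross-monomerization coefficients for its shared
    bonds, or a single-cell *intra* channel (``ch_b == -1``) carrying the
    within-cell reaction coefficients.  The kernel evaluates the combined
    propensity from the current counts and resolves the sub-event after
    selection.
    """

    q: np.ndarray
    is_central: np.ndarray
    ch_a: np.ndarray
    ch_b: np.ndarray
    g_hop_m: np.ndarray
    g_hop_d: np.ndarray
    g_dim: np.ndarray
    g_mono: np.ndarray
    csr_ptr: np.ndarray
    csr_idx: np.ndarray


def build_channel_table(geom: Geometry, mesh: Mesh, rates) -> ChannelTable:
    n = geom.n_side
    st = geom.site_type
    cell_of = mesh.cell_of
    q = mesh.q
    ctype = mesh.cell_type

    # accumulate per adjacent cell pair: bond count + summed hop conductances
    acc: dict[tuple[int, int], list[float]] = {}
    for i, j, axis in _iter_bonds(n):
        a, b = int(cell_of[i]), int(cell_of[j])
        if a == b:
            continue
        if a > b:
            a, b = b, a
            i, j = j, i
        span_a = int(mesh.span_c[a] if axis == 1 else mesh.span_r[a])
        span_b = int(mesh.span_c[b] if axis == 1 else mesh.span_r[b])
        t_i, t_j = int(st[i]), int(st[j])
        gm = bond_conductance(
            span_a,
            rates.hop_rate(Species.MONOMER, ctype[a], ctype[a]),
            span_b,
            rates.hop_rate(Species.MONOMER, ctype[b], ctype[b]),
            rates.hop_rate(Species.MONOMER, t_i, t_j),
        )
        gd = bond_conductance(
            span_a,
            rates.hop_rate(Species.DIMER, ctype[a], ctype[a]),
            span_b,
            rates.hop_rate(Species.DIMER, ctype[b], ctype[b]),
            rates.hop_rate(Species.DIMER, t_i, t_j),
        )
        ent = acc.setdefault((a, b), [0.0, 0.0, 0])
        ent[0] += gm
        ent[1] += gd
        ent[2] += 1

    k_d = rates.k_d_eff
    k_m = rates.k_m_eff
    ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono = [], [], [], [], [], []
    for (a, b), (gm_sum, gd_sum, ell) in sorted(acc.items()):
        qa, qb = int(q[a]), int(q[b])
        gm = gm_sum / (qa * qb)
        gd = gd_sum / (qa * qb)
        gdim = k_d * ell / (qa * qb)
        gmono = k_m * ell / (qa * qb)
        if gm == 0.0 and gd == 0.0 and gdim == 0.0 and gmono == 0.0:
            continue
        ch_a.append(a)
        ch_b.append(b)
        g_hop_m.append(gm)
        g_hop_d.append(gd)
        g_dim.append(gdim)
        g_mono.append(gmono)

    for k in range(mesh.n_cells):
        qk, Ek = int(q[k]), int(mesh.internal_edges[k])
        if qk < 2 or Ek == 0:
            continue
        gdim = k_d * Ek / (qk * (qk - 1))
        gmono = k_m * 2 * Ek / (qk * (qk - 1))
        if gdim == 0.0 and gmono == 0.0:
            continue
        ch_a.append(k)
        ch_b.append(-1)
        g_hop_m.append(0.0)
        g_hop_d.append(0.0)
        g_dim.append(gdim)
        g_mono.append(gmono)

    ch_a = np.array(ch_a, dtype=np.int64)
    ch_b = np.array(ch_b, dtype=np.int64)
    n_ch = ch_a.size

    # CSR: cell -> channels whose propensity depends on that cell's counts
    deps: list[list[int]] = [[] for _ in range(mesh.n_cells)]
    for c in range(n_ch):
        deps[ch_a[c]].append(c)
        if ch_b[c] >= 0:
            deps[ch_b[c]].append(c)
    csr_ptr = np.zeros(mesh.n_cells + 1, dtype=np.int64)
    for k in range(mesh.n_cells):
        csr_ptr[k + 1] = csr_ptr[k] + len(deps[k])
    csr_idx = np.empty(csr_ptr[-1], dtype=np.int64)
    pos = 0
    for k in range(mesh.n_cells):
        for c in deps[k]:
            csr_idx[pos] = c
            pos += 1

    return ChannelTable(
        q=q.astype(np.int64),
        is_central=(ctype == int(SiteType.CENTRAL)).astype(np.uint8),
        ch_a=ch_a,
        ch_b=ch_b,
        g_hop_m=np.array(g_hop_m, dtype=np.float64),
        g_hop_d=np.array(g_hop_d, dtype=np.float64),
        g_dim=np.array(g_dim, dtype=np.float64),
        g_mono=np.array(g_mono, dtype=np.float64),
        csr_ptr=csr_ptr,
        csr_idx=csr_idx,
    )


def counts_from_microstate(mesh: Mesh, state: MicroState):
    """Per-cell (N_M, N_D) from a microscopic occupancy state."""
    nm = np.zeros(mesh.n_cells, dtype=np.int64)
    nd = np.zeros(mesh.n_cells, dtype=np.int64)
    cells = mesh.cell_of.reshape(-1)
    occ = state.occ.reshape(-1)
    np.add.at(nm, cells[occ == int(Species.MONOMER)], 1)
    np.add.at(nd, cells[occ == int(Species.DIMER)], 1)
    return nm, nd


def coarse_count(mesh: Mesh, state: MicroState, cell: int, species: Species) -> int:
    """Number of particles of ``species`` in ``cell`` (sum of occupancies)."""
    nm, nd = counts_from_microstate(mesh, state)
    return int(nm[cell] if species == Species.MONOMER else nd[cell])
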