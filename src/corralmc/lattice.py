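"""Periodic square lattice, membrane domain types, and microscopic occupancy state.

The membrane is discretized as an ``n x n`` square lattice with periodic
boundaries.  Each site carries a fixed type — ``CENTRAL`` for the high-density
microdomain (raft / clathrin pit / corral interior) or ``OUTER`` for the
surrounding low-density membrane — and holds at most one species: a receptor
monomer (M) or a receptor dimer (D).  A dimer occupies a single site but
counts as two receptors, so the conserved receptor number is ``N_M + 2 N_D``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Species",
    "SiteType",
    "Geometry",
    "MicroState",
    "build_geometry",
    "neighbor_sites",
    "receptor_counts",
    "write_snapshot",
    "read_snapshot",
]


class Species(IntEnum):
    """Occupant of a lattice site; vacancy is the absence of a species."""

    MONOMER = 1
    DIMER = 2


class SiteType(IntEnum):
    """Membrane region a site belongs to (fixed for the whole run)."""

    OUTER = 0
    CENTRAL = 1


VACANT = 0  # occupancy code for an empty site


class ConfigurationError(ValueError):
    """Raised for inconsistent geometry or scenario configuration."""


@dataclass(frozen=True)
class Geometry:
    """Periodic square lattice geometry with typed high-density rectangles.

    Parameters are in nanometres; sites are indexed ``(row, col)``, 0-based,
    row-major, with the origin at the box corner.  ``site_type`` is an
    ``(n_side, n_side)`` array of :class:`SiteType` codes.
    """

    box_nm: float
    lattice_nm: float
    n_side: int
    site_type: np.ndarray
    domain_rects: tuple[tuple[int, int, int, int], ...]  # (row0, col0, h, w) in sites

    @property
    def n_sites(self) -> int:
        return self.n_side * self.n_side

    @property
    def n_central(self) -> int:
        return int(np.count_nonzero(self.site_type == SiteType.CENTRAL))

    @property
    def box_area_um2(self) -> float:
        return (self.box_nm * 1e-3) ** 2

    @property
    def site_area_um2(self) -> float:
        return (self.lattice_nm * 1e-3) ** 2

    @property
    def central_mask(self) -> np.ndarray:
        return self.site_type == SiteType.CENTRAL

    def site_index(self, row: int, col: int) -> int:
        return row * self.n_side + col


def _check_multiple(value_nm: float, a_nm: float, what: str) -> int:
    k = value_nm / a_nm
    if abs(k - round(k)) > 1e-9 or value_nm <= 0:
        raise ConfigurationError(
            f"{what} ({value_nm} nm) must be a positive multiple of the "
            f"lattice constant ({a_nm} nm)"
        )
    return int(round(k))


def build_geometry(
    box_nm: float,
    lattice_nm: float,
    domain_specs: list[tuple[tuple[float, float], float]] | None = None,
) -> Geometry:
    """Build a periodic lattice with CENTRAL high-density rectangles.

    Parameters
    ----------
    box_nm:
        Side of the square simulation box in nm.
    lattice_nm:
        Lattice constant ``a`` (site spacing) in nm.
    domain_specs:
        List of ``((x_nm, y_nm), side_nm)`` — origin and side of each square
        high-density domain, nm from the box corner.  Domains must lie within
        the box and must not overlap.
    """
    n = _check_multiple(box_nm, lattice_nm, "box side")
    site_type = np.zeros((n, n), dtype=np.uint8)
    rects = []
    for (x_nm, y_nm), side_nm in domain_specs or []:
        w = _check_multiple(side_nm, lattice_nm, "domain side")
        col0 = _check_multiple(x_nm, lattice_nm, "domain x origin") if x_nm else 0
        row0 = _check_multiple(y_nm, lattice_nm, "domain y origin") if y_nm else 0
        if row0 + w > n or col0 + w > n:
            raise ConfigurationError("high-density domain extends outside the box")
        block = site_type[row0 : row0 + w, col0 : col0 + w]
        if np.any(block == SiteType.CENTRAL):
            raise ConfigurationError("high-density domains overlap")
        block[:] = SiteType.CENTRAL
        rects.append((row0, col0, w, w))
    return Geometry(
        box_nm=float(box_nm),
        lattice_nm=float(lattice_nm),
        n_side=n,
        site_type=site_type,
        domain_rects=tuple(rects),
    )


def centered_domain_spec(box_nm: float, lattice_nm: float, side_nm: float):
    """Origin of a domain of ``side_nm`` centred in the box, snapped to sites."""
    n = _check_multiple(box_nm, lattice_nm, "box side")
    w = _check_multiple(side_nm, lattice_nm, "domain side")
    off = ((n - w) // 2) * lattice_nm
    return ((off, off), side_nm)


def neighbor_sites(geom: Geometry, site: tuple[int, int]) -> list[tuple[int, int]]:
    """The 4 von-Neumann neighbors of ``site`` with periodic wrap-around."""
    r, c = site
    n = geom.n_side
    if not (0 <= r < n and 0 <= c < n):
        raise IndexError(f"site {site} outside {n}x{n} lattice")
    return [((r - 1) % n, c), ((r + 1) % n, c), (r, (c - 1) % n), (r, (c + 1) % n)]


@dataclass
class MicroState:
    """Per-site occupancy with cached region counts and simulation time.

    ``occ`` holds 0 (vacant), 1 (monomer) or 2 (dimer) per site; this is the
    concrete form of the occupancy indicator sigma_i^{S,phi} (1 iff species S
    sits on site i of type phi).  Receptor number ``N_M + 2 N_D`` is invariant
    under every event.
    """

    geom: Geometry
    occ: np.ndarray
    t: float = 0.0
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def empty(cls, geom: Geometry) -> "MicroState":
        return cls(geom=geom, occ=np.zeros((geom.n_side, geom.n_side), dtype=np.int8))

    def place(self, site: tuple[int, int], species: Species | int) -> None:
        if self.occ[site] != VACANT:
            raise ValueError(f"site {site} already occupied")
        self.occ[site] = int(species)
        self._cache.clear()

    def clear_cache(self) -> None:
        self._cache.clear()

    def counts(self, region_mask: np.ndarray | None = None):
        key = "all" if region_mask is None else id(region_mask)
        if key not in self._cache:
            occ = self.occ if region_mask is None else self.occ[region_mask]
            n_m = int(np.count_nonzero(occ == Species.MONOMER))
            n_d = int(np.count_nonzero(occ == Species.DIMER))
            self._cache[key] = (n_m, n_d, n_m + 2 * n_d)
        return self._cache[key]

    @property
    def n_receptors(self) -> int:
        return self.counts()[2]

    def copy(self) -> "MicroState":
        return MicroState(geom=self.geom, occ=self.occ.copy(), t=self.t)


def receptor_counts(state: MicroState, region_mask: np.ndarray | None = None):
    """``(N_M, N_D, N_M + 2 N_D)`` restricted to ``region_mask`` (boolean array)."""
    return state.counts(region_mask)


_CHARS = {VACANT: ".", int(Species.MONOMER): "M", int(Species.DIMER): "D"}
_CODES = {v: k for k, v in _CHARS.items()}


def write_snapshot(path, state: MicroState, seed: int | None = None) -> None:
    """Write a plain-text snapshot: one JSON header line, then one row per line."""
    g = state.geom
    header = {
        "time": state.t,
        "seed": seed,
        "box_nm": g.box_nm,
        "lattice_nm": g.lattice_nm,
        "n_side": g.n_side,
        "domain_rects": [list(r) for r in g.domain_rects],
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for row in state.occ:
            fh.write("".join(_CHARS[int(v)] for v in row) + "\n")


def read_snapshot(path) -> MicroState:
    with open(path) as fh:
        header = json.loads(fh.readline())
        rows = [line.strip() for line in fh if line.strip()]
    specs = [
        ((r[1] * header["lattice_nm"], r[0] * header["lattice_nm"]), r[2] * header["lattice_nm"])
        for r in header["domain_rects"]
    ]
    geom = build_geometry(header["box_nm"], header["lattice_nm"], specs)
    occ = np.array([[_CODES[ch] for ch in row] for row in rows], dtype=np.int8)
    if occ.shape != (geom.n_side, geom.n_side):
        raise ConfigurationError("snapshot grid does not match header geometry")
    state = MicroState(geom=geom, occ=occ, t=header["time"])
    return state
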