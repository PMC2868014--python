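"""Experiment configurations: geometry, rates, initial placement, schedules.

The canonical setup is a 240 x 240 nm periodic membrane patch (lattice
constant 6 nm, 40 x 40 sites) containing one centred high-density domain.
Two families of scenarios are provided:

* the pure-diffusion scenario (single mobile species, domain initially fully
  covered) used to validate the coarse-grained diffusion rates; and
* the reaction-diffusion scenario (all receptors start as monomers at random
  sites of the high-density domain — the worst case for cluster lifetime)
  with the nominal EGFR rate table, an overall receptor density in
  receptors/um^2, and optional sensitivity overrides (domain size, density,
  dimer barrier switch, rate multipliers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .lattice import (
    ConfigurationError,
    Geometry,
    MicroState,
    Species,
    build_geometry,
    centered_domain_spec,
)
from .kinetics import RateTable, diffusion_only_rates

__all__ = [
    "Scenario",
    "diffusion_only_scenario",
    "reaction_diffusion_scenario",
    "make_fixture",
    "domain_density_grid",
    "rate_sensitivity_grid",
]


def log_sample_times(t_first: float, t_end: float, n: int) -> list[float]:
    """t = 0 plus ``n`` log-spaced samples in [t_first, t_end]."""
    return [0.0] + list(np.geomspace(t_first, t_end, n))


@dataclass
class Scenario:
    """A complete, serializable run configuration."""

    box_nm: float = 240.0
    lattice_nm: float = 6.0
    domains: list = field(default_factory=list)  # [{x_nm, y_nm, side_nm}]
    rates: RateTable = field(default_factory=RateTable)
    density_um2: float | None = None
    placement: str = "random_central"  # or "full_cover"
    sample_times: list = field(default_factory=lambda: log_sample_times(1e-3, 200.0, 120))
    cg_cell_sites: int = 8

    @property
    def t_end(self) -> float:
        return float(self.sample_times[-1])

    def build_geometry(self) -> Geometry:
        specs = [((d["x_nm"], d["y_nm"]), d["side_nm"]) for d in self.domains]
        return build_geometry(self.box_nm, self.lattice_nm, specs)

    def n_receptors(self, geom: Geometry | None = None) -> int:
        geom = geom or self.build_geometry()
        if self.placement == "full_cover":
            return geom.n_central
        if self.density_um2 is None:
            raise ConfigurationError("random_central placement needs density_um2")
        n = int(round(self.density_um2 * geom.box_area_um2))
        if n > geom.n_central:
            raise ConfigurationError(
                f"{n} receptors exceed the {geom.n_central}-site capacity of the "
                "high-density region"
            )
        if n < 1:
            raise ConfigurationError("density rounds to zero receptors")
        return n

    def initial_state(self, geom: Geometry, rng: np.random.Generator) -> MicroState:
        """Seeded initial condition; all receptors start as monomers."""
        state = MicroState.empty(geom)
        central = np.argwhere(geom.central_mask)
        if self.placement == "full_cover":
            for r, c in central:
                state.occ[r, c] = Species.MONOMER
        elif self.placement == "random_central":
            n = self.n_receptors(geom)
            chosen = rng.choice(len(central), size=n, replace=False)
            for idx in chosen:
                r, c = central[idx]
                state.occ[r, c] = Species.MONOMER
        else:
            raise ConfigurationError(f"unknown placement {self.placement!r}")
        state.clear_cache()
        return state

    # -- round-trippable config ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "geometry": {
                "box_nm": self.box_nm,
                "lattice_nm": self.lattice_nm,
                "domains": [dict(d) for d in self.domains],
            },
            "rates": self.rates.to_dict(),
            "density_um2": self.density_um2,
            "placement": self.placement,
            "sample_times": [float(t) for t in self.sample_times],
            "cg_cell_sites": self.cg_cell_sites,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        g = d["geometry"]
        return cls(
            box_nm=g["box_nm"],
            lattice_nm=g["lattice_nm"],
            domains=list(g.get("domains", [])),
            rates=RateTable.from_dict(d["rates"]),
            density_um2=d.get("density_um2"),
            placement=d.get("placement", "random_central"),
            sample_times=list(d["sample_times"]),
            cg_cell_sites=d.get("cg_cell_sites", 8),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _centered_domains(box_nm, lattice_nm, side_nm):
    (x, y), s = centered_domain_spec(box_nm, lattice_nm, side_nm)
    return [{"x_nm": x, "y_nm": y, "side_nm": s}]


def diffusion_only_scenario(t_end: float = 0.1, n_samples: int = 14) -> Scenario:
    """Pure-diffusion validation scenario: fully covered 48 nm domain.

    A single mobile species (modelled as the monomer) with the diffusion-only
    rate set: in-domain hops at 2.5e5 /s, barrier hops at 2.5e2 /s, no
    reactions.  Starts with every high-density site occupied.
    """
    return Scenario(
        domains=_centered_domains(240.0, 6.0, 48.0),
        rates=diffusion_only_rates(),
        placement="full_cover",
        sample_times=log_sample_times(1e-4, t_end, n_samples),
    )


def reaction_diffusion_scenario(
    density_um2: float = 150.0,
    domain_side_nm: float = 48.0,
    dimer_barrier: bool = True,
    multipliers: dict | None = None,
    t_end: float = 200.0,
    n_samples: int = 120,
) -> Scenario:
    """The EGFR cluster-dissipation scenario.

    Nominal rates, receptors initialized as monomers at random distinct sites
    of the centred high-density domain.  ``multipliers`` scales individual
    rate constants (e.g. ``{"k_d": 10.0}``) for sensitivity sweeps;
    ``dimer_barrier=False`` disables dimer barrier hopping entirely.
    """
    rates = RateTable(
        dimer_barrier_enabled=dimer_barrier, multipliers=dict(multipliers or {})
    )
    return Scenario(
        domains=_centered_domains(240.0, 6.0, domain_side_nm),
        rates=rates,
        density_um2=density_um2,
        placement="random_central",
        sample_times=log_sample_times(1e-3, t_end, n_samples),
    )


def make_fixture(kind: str, seed: int = 0):
    """Small seeded states for unit and property tests.

    ``tiny_lattice``: 3x3 homogeneous periodic lattice with 2 monomers (the
    enumerable configuration space of the master-equation oracle).
    ``worked_pair``: 4x4 lattice with one adjacent monomer pair.
    ``random_state``: 8x8 lattice with a 50%-CENTRAL block and ~25% fill of
    monomers and dimers.
    """
    rng = np.random.default_rng(seed)
    if kind == "tiny_lattice":
        geom = build_geometry(18.0, 6.0, [])
        state = MicroState.empty(geom)
        sites = rng.choice(9, size=2, replace=False)
        for s in sites:
            state.occ[s // 3, s % 3] = Species.MONOMER
        return state, geom
    if kind == "worked_pair":
        geom = build_geometry(24.0, 6.0, [])
        state = MicroState.empty(geom)
        state.occ[1, 1] = Species.MONOMER
        state.occ[1, 2] = Species.MONOMER
        return state, geom
    if kind == "random_state":
        geom = build_geometry(48.0, 6.0, [((0.0, 0.0), 24.0)])
        state = MicroState.empty(geom)
        n = geom.n_side
        for s in rng.choice(n * n, size=(n * n) // 4, replace=False):
            state.occ[s // n, s % n] = rng.choice(
                [int(Species.MONOMER), int(Species.DIMER)], p=[0.7, 0.3]
            )
        state.clear_cache()
        return state, geom
    raise ValueError(f"unknown fixture kind {kind!r}")


def domain_density_grid(t_end: float = 200.0) -> list[dict]:
    """Sensitivity grid: domain size x overall density x dimer barrier switch."""
    grid = []
    for side in (48.0, 24.0):
        for dens in (150.0, 833.0):
            for barrier in (True, False):
                grid.append(
                    {
                        "name": f"side{side:g}_dens{dens:g}_{'bar' if barrier else 'nobar'}",
                        "density_um2": dens,
                        "domain_side_nm": side,
                        "dimer_barrier": barrier,
                        "multipliers": {},
                        "t_end": t_end,
                    }
                )
    return grid


def rate_sensitivity_grid(factors=(2.0, 10.0), t_end: float = 200.0) -> list[dict]:
    """Rate-constant sensitivity grid around the high-density nominal case.

    Nominal: ~833 receptors/um^2, 48 nm domain, dimer barrier hopping
    disabled; each of k_M, k_D and the monomer barrier rate is increased by
    the given factors.
    """
    base = {
        "density_um2": 833.0,
        "domain_side_nm": 48.0,
        "dimer_barrier": False,
        "t_end": t_end,
    }
    grid = [dict(base, name="nominal", multipliers={})]
    for key, label in (
        ("k_m", "kM"),
        ("k_d", "kD"),
        ("gamma_m_barrier", "DMbar"),
    ):
        for f in factors:
            grid.append(dict(base, name=f"{label}_x{f:g}", multipliers={key: f}))
    return grid
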