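"""Microscopic propensity kernels and event-channel enumeration.

Three elementary processes drive the model (nominal rate constants from the
EGFR diffusion-reaction parameter set):

* hopping of a monomer or dimer to a vacant neighboring site, at a rate that
  depends on the species and on whether the move stays inside one membrane
  region or crosses the barrier between the high-density domain and the
  outer membrane;
* dimerization ``M + M -> D + *`` of two adjacent monomers (the dimer is
  placed on one of the two sites by a fair coin flip, the other is freed);
* monomerization ``D + * -> M + M`` of a dimer into a vacant neighboring
  site, one channel per (dimer, vacant neighbor) pair at rate ``k_M`` each.

The channel list built here is the direct-method reference path: the fast
engines assemble their own channel tables (see :mod:`corralmc.coarse`) and
are cross-checked against this enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import Geometry, MicroState, Species, SiteType, VACANT, neighbor_sites

__all__ = [
    "RateTable",
    "Channel",
    "HOP",
    "DIMERIZE",
    "MONOMERIZE",
    "hop_propensity",
    "dimerization_propensity",
    "monomerization_propensity",
    "enumerate_channels",
    "total_propensity",
    "apply_channel",
]

HOP = "HOP"
DIMERIZE = "DIMERIZE"
MONOMERIZE = "MONOMERIZE"


@dataclass(frozen=True)
class RateTable:
    """All rate constants (s^-1) plus sweep multipliers and switches.

    Defaults are the nominal EGFR diffusion-reaction constants: fast in-domain
    diffusion, a barrier ~3 orders of magnitude slower for monomers and ~6
    orders slower for dimers, slow dimer dissociation and fast association.
    ``multipliers`` scale individual base constants (keys are field names),
    which is how the x2 / x10 sensitivity sweeps are expressed.
    """

    gamma_m_central: float = 2.50e5
    gamma_m_outer: float = 2.50e5
    gamma_d_central: float = 1.25e5
    gamma_d_outer: float = 1.25e5
    gamma_m_barrier: float = 2.50e2
    gamma_d_barrier: float = 1.25e-1
    k_m: float = 1.70e-2
    k_d: float = 5.67e2
    dimer_barrier_enabled: bool = True
    multipliers: dict = field(default_factory=dict)

    def _val(self, name: str) -> float:
        v = getattr(self, name) * self.multipliers.get(name, 1.0)
        if v < 0:
            raise ValueError(f"rate {name} must be non-negative")
        return v

    def hop_rate(self, species: int, type1: int, type2: int) -> float:
        """Hop rate for ``species`` moving from a site of ``type1`` to ``type2``.

        A channel whose two sites have different types is a barrier channel
        regardless of direction; otherwise the in-domain rate of ``type1``
        applies.
        """
        if species == Species.MONOMER:
            if type1 != type2:
                return self._val("gamma_m_barrier")
            return self._val(
                "gamma_m_central" if type1 == SiteType.CENTRAL else "gamma_m_outer"
            )
        if type1 != type2:
            if not self.dimer_barrier_enabled:
                return 0.0
            return self._val("gamma_d_barrier")
        return self._val(
            "gamma_d_central" if type1 == SiteType.CENTRAL else "gamma_d_outer"
        )

    @property
    def k_m_eff(self) -> float:
        return self._val("k_m")

    @property
    def k_d_eff(self) -> float:
        return self._val("k_d")

    def with_multipliers(self, **mult: float) -> "RateTable":
        merged = dict(self.multipliers)
        merged.update(mult)
        return replace(self, multipliers=merged)

    def to_dict(self) -> dict:
        return {
            "gamma_m_central": self.gamma_m_central,
            "gamma_m_outer": self.gamma_m_outer,
            "gamma_d_central": self.gamma_d_central,
            "gamma_d_outer": self.gamma_d_outer,
            "gamma_m_barrier": self.gamma_m_barrier,
            "gamma_d_barrier": self.gamma_d_barrier,
            "k_m": self.k_m,
            "k_d": self.k_d,
            "dimer_barrier_enabled": self.dimer_barrier_enabled,
            "multipliers": dict(self.multipliers),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateTable":
        return cls(**d)


#: Table 1-style parameters for the pure-diffusion model: a single mobile
#: species (represented as the monomer), no reactions.
def diffusion_only_rates() -> RateTable:
    return RateTable(
        gamma_m_central=2.50e5,
        gamma_m_outer=2.50e5,
        gamma_m_barrier=2.50e2,
        gamma_d_central=0.0,
        gamma_d_outer=0.0,
        gamma_d_barrier=0.0,
        k_m=0.0,
        k_d=0.0,
    )


@dataclass(frozen=True)
class Channel:
    """One stochastic event channel.

    ``sites`` is an ordered pair for HOP (from, to) and MONOMERIZE (dimer,
    vacant target), and a row-major-sorted unordered pair for DIMERIZE.
    """

    kind: str
    sites: tuple[tuple[int, int], tuple[int, int]]
    propensity: float


def _types(geom: Geometry, i1, i2) -> tuple[int, int]:
    return int(geom.site_type[i1]), int(geom.site_type[i2])


def _require_adjacent(geom: Geometry, i1, i2) -> None:
    if i2 not in neighbor_sites(geom, i1):
        raise ValueError(f"sites {i1} and {i2} are not adjacent")


def hop_propensity(state: MicroState, rates: RateTable, i1, i2) -> float:
    """Propensity of the occupant of ``i1`` hopping to ``i2`` (0 if blocked)."""
    _require_adjacent(state.geom, i1, i2)
    s = int(state.occ[i1])
    if s == VACANT or state.occ[i2] != VACANT:
        return 0.0
    t1, t2 = _types(state.geom, i1, i2)
    return rates.hop_rate(s, t1, t2)


def dimerization_propensity(state: MicroState, rates: RateTable, i1, i2) -> float:
    """Propensity of the unordered adjacent pair ``(i1, i2)`` dimerizing."""
    _require_adjacent(state.geom, i1, i2)
    if state.occ[i1] == Species.MONOMER and state.occ[i2] == Species.MONOMER:
        return rates.k_d_eff
    return 0.0


def monomerization_propensity(state: MicroState, rates: RateTable, i1, i2) -> float:
    """Propensity of the dimer at ``i1`` dissociating into vacant ``i2``."""
    _require_adjacent(state.geom, i1, i2)
    if state.occ[i1] == Species.DIMER and state.occ[i2] == VACANT:
        return rates.k_m_eff
    return 0.0


def enumerate_channels(state: MicroState, rates: RateTable) -> list[Channel]:
    """All event channels with nonzero structural support in ``state``.

    One channel per (occupied site, vacant neighbor) hop opportunity, one per
    unordered adjacent monomer-monomer pair, one per (dimer, vacant neighbor)
    dissociation target.  Channels with zero propensity (e.g. a disabled dimer
    barrier) are included only if their rate constant is nonzero.
    """
    geom = state.geom
    occ = state.occ
    chans: list[Channel] = []
    occupied = np.argwhere(occ != VACANT)
    for r, c in occupied:
        i1 = (int(r), int(c))
        s = int(occ[i1])
        for i2 in neighbor_sites(geom, i1):
            o2 = int(occ[i2])
            t1, t2 = _types(geom, i1, i2)
            if o2 == VACANT:
                rate = rates.hop_rate(s, t1, t2)
                if rate > 0.0:
                    chans.append(Channel(HOP, (i1, i2), rate))
                if s == Species.DIMER and rates.k_m_eff > 0.0:
                    chans.append(Channel(MONOMERIZE, (i1, i2), rates.k_m_eff))
            elif (
                s == Species.MONOMER
                and o2 == Species.MONOMER
                and i1 < i2  # one channel per unordered pair
                and rates.k_d_eff > 0.0
            ):
                chans.append(Channel(DIMERIZE, (i1, i2), rates.k_d_eff))
    return chans


def total_propensity(channels: list[Channel]) -> float:
    return float(sum(ch.propensity for ch in channels))


def apply_channel(
    state: MicroState, channel: Channel, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    """Fire ``channel`` in place; returns the sites whose occupancy changed.

    Preconditions are asserted: a stale channel indicates a bookkeeping bug in
    the caller.  Dimerization places the product dimer on one of the two
    parent sites chosen by a fair coin flip.
    """
    i1, i2 = channel.sites
    occ = state.occ
    if channel.kind == HOP:
        if occ[i1] == VACANT or occ[i2] != VACANT:
            raise RuntimeError(f"stale HOP channel {channel}")
        occ[i2] = occ[i1]
        occ[i1] = VACANT
    elif channel.kind == DIMERIZE:
        if occ[i1] != Species.MONOMER or occ[i2] != Species.MONOMER:
            raise RuntimeError(f"stale DIMERIZE channel {channel}")
        keep, free = (i1, i2) if rng.random() < 0.5 else (i2, i1)
        occ[keep] = Species.DIMER
        occ[free] = VACANT
    elif channel.kind == MONOMERIZE:
        if occ[i1] != Species.DIMER or occ[i2] != VACANT:
            raise RuntimeError(f"stale MONOMERIZE channel {channel}")
        occ[i1] = Species.MONOMER
        occ[i2] = Species.MONOMER
    else:  # pragma: no cover
        raise ValueError(f"unknown channel kind {channel.kind}")
    state.clear_cache()
    return (i1, i2)
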