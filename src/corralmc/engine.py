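"""Event-driven stochastic simulation: waiting times, propensity-tree
selection, a direct-method reference engine, and the production run wrapper.

The next-event time follows the Gillespie prescription ``tau = ln(1/u)/a_0``
with ``a_0`` the total propensity, and the event is drawn with probability
proportional to its propensity.  Selection and update use a complete binary
sum tree over the channel propensities, O(log n) per event.

Two execution paths exist on purpose:

* :func:`run_reference` — a transparent direct-method loop over the
  microscopic channel list re-enumerated every event.  It is slow and is used
  as an independent oracle on tiny lattices and in unit tests.
* :func:`simulate` / :func:`simulate_replicates` — the production path: a
  mesh-agnostic channel table (:mod:`corralmc.coarse`) executed by a compiled
  event loop (:mod:`corralmc._kernel`).  All three engines (kmc / ucgmc /
  acgmc) differ only in the mesh handed to the table builder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import MicroState
from .kinetics import (
    RateTable,
    apply_channel,
    enumerate_channels,
    total_propensity,
)

__all__ = [
    "EventTree",
    "waiting_time",
    "select_channel",
    "run_reference",
    "simulate",
    "simulate_replicates",
    "ENGINES",
]

ENGINES = ("kmc", "ucgmc", "acgmc")


def waiting_time(a0: float, u: float) -> float:
    """Exponential waiting time ``ln(1/u)/a0`` for uniform ``u`` in (0, 1]."""
    if a0 <= 0.0:
        raise ValueError("waiting_time requires a0 > 0 (a0 = 0 is absorbing)")
    return math.log(1.0 / u) / a0


class EventTree:
    """Complete binary sum tree over channel propensities.

    Leaves hold per-channel propensities, internal nodes subtree sums, the
    root the total ``a_0``.  ``select(r)`` descends root-to-leaf so channel
    ``m`` is returned with probability ``p_m / a_0`` for uniform
    ``r in [0, a_0)``.
    """

    def __init__(self, propensities):
        p = np.asarray(propensities, dtype=np.float64)
        if p.size == 0:
            raise ValueError("EventTree needs at least one channel")
        m = 1
        while m < p.size:
            m *= 2
        self.m = m
        self.n = p.size
        self.tree = np.zeros(2 * m, dtype=np.float64)
        self.tree[m : m + p.size] = p
        for i in range(m - 1, 0, -1):
            self.tree[i] = self.tree[2 * i] + self.tree[2 * i + 1]

    @property
    def total(self) -> float:
        return float(self.tree[1])

    def update(self, index: int, propensity: float) -> None:
        i = self.m + index
        delta = propensity - self.tree[i]
        while i >= 1:
            self.tree[i] += delta
            i //= 2

    def select(self, r: float) -> int:
        """Leaf index whose cumulative interval contains ``r``."""
        if not 0.0 <= r < self.total:
            raise ValueError(f"selection point {r} outside [0, {self.total})")
        i = 1
        while i < self.m:
            i *= 2
            if r >= self.tree[i]:
                r -= self.tree[i]
                i += 1
        idx = i - self.m
        return min(idx, self.n - 1)

    def rebuild(self, propensities) -> None:
        p = np.asarray(propensities, dtype=np.float64)
        self.tree[:] = 0.0
        self.tree[self.m : self.m + p.size] = p
        for i in range(self.m - 1, 0, -1):
            self.tree[i] = self.tree[2 * i] + self.tree[2 * i + 1]


def select_channel(tree: EventTree, r: float) -> int:
    return tree.select(r)


def run_reference(
    state: MicroState,
    rates: RateTable,
    t_end: float,
    rng: np.random.Generator,
    sample_times=None,
    on_event=None,
    max_events: int | None = None,
):
    """Direct-method KMC: re-enumerate all channels every event.

    Mutates ``state`` in place up to ``t_end`` (or ``max_events``).  If
    ``sample_times`` is given, returns the list of state copies observed
    immediately before the first event after each sample time; otherwise
    returns the number of events executed.  ``on_event(t, channel)`` is
    called after each firing (used e.g. to accumulate displacements).
    """
    samples = []
    s_idx = 0
    times = list(sample_times) if sample_times is not None else []
    n_events = 0
    while True:
        chans = enumerate_channels(state, rates)
        a0 = total_propensity(chans)
        if a0 <= 0.0:  # absorbing state: freeze remaining samples
            while s_idx < len(times):
                frozen = state.copy()
                frozen.t = times[s_idx]
                samples.append(frozen)
                s_idx += 1
            break
        tau = waiting_time(a0, 1.0 - rng.random())
        t_next = state.t + tau
        while s_idx < len(times) and times[s_idx] <= t_next:
            snap = state.copy()
            snap.t = times[s_idx]
            samples.append(snap)
            s_idx += 1
        if t_next >= t_end and s_idx >= len(times):
            state.t = t_end
            break
        state.t = t_next
        r = rng.random() * a0
        acc = 0.0
        chosen = chans[-1]
        for ch in chans:
            acc += ch.propensity
            if r < acc:
                chosen = ch
                break
        apply_channel(state, chosen, rng)
        n_events += 1
        if on_event is not None:
            on_event(state.t, chosen)
        if max_events is not None and n_events >= max_events:
            break
    return samples if sample_times is not None else n_events


# ---------------------------------------------------------------------------
# Production path: compiled kernel over a mesh channel table.
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Tidy trajectory table plus run metadata.

    ``frame`` columns: time_s, region, n_monomer, n_dimer, n_receptors,
    replicate, engine.  ``meta`` echoes the realized configuration (counts,
    seeds, event totals) so runs are auditable.
    """

    frame: pd.DataFrame
    meta: dict


def _replicate_seeds(base_seed: int, replicate: int) -> tuple[np.random.SeedSequence, int]:
    """Deterministic per-replicate RNG roots.

    A replicate's placement generator and its kernel stream are spawned from
    ``SeedSequence(base_seed)`` child ``replicate`` — reproducible and safe to
    parallelize across replicates.
    """
    child = np.random.SeedSequence(entropy=base_seed, spawn_key=(replicate,))
    place_ss, kernel_ss = child.spawn(2)
    kernel_seed = int(kernel_ss.generate_state(1)[0] & 0x7FFFFFFF)
    return place_ss, kernel_seed


def simulate(
    scenario,
    engine: str = "acgmc",
    base_seed: int = 0,
    replicate: int = 0,
    stop_below_ratio: float | None = None,
) -> Trajectory:
    """Run one replicate of ``scenario`` with the chosen engine.

    ``stop_below_ratio``: optionally stop once the central-region density
    ratio has stayed below this value for 3 consecutive samples (the cluster
    has dissipated); remaining samples repeat the frozen state and the stop is
    flagged in the metadata.
    """
    from . import coarse
    from ._kernel import run_kernel

    if engine not in ENGINES:
        raise ValueError(f"engine must be one of {ENGINES}, got {engine!r}")
    geom = scenario.build_geometry()
    rates = scenario.rates
    mesh_kind = {"kmc": "fine", "ucgmc": "uniform", "acgmc": "adaptive"}[engine]
    mesh = coarse.build_mesh(geom, mesh_kind, cg_cell_sites=scenario.cg_cell_sites)
    table = coarse.build_channel_table(geom, mesh, rates)

    place_ss, kernel_seed = _replicate_seeds(base_seed, replicate)
    state = scenario.initial_state(geom, np.random.default_rng(place_ss))
    n_m0, n_d0, n_rec0 = state.counts()
    nm, nd = coarse.counts_from_microstate(mesh, state)

    sample_times = np.asarray(scenario.sample_times, dtype=np.float64)
    if np.any(np.diff(sample_times) < 0):
        raise ValueError("sample_times must be sorted")

    if stop_below_ratio is not None:
        # ratio < x  <=>  central receptors < x * rho_overall * A_central
        stop_count = (
            stop_below_ratio * n_rec0 * geom.n_central / geom.n_sites
        )
    else:
        stop_count = -1.0

    out = run_kernel(
        table.q,
        table.is_central,
        nm.astype(np.int64),
        nd.astype(np.int64),
        table.ch_a,
        table.ch_b,
        table.g_hop_m,
        table.g_hop_d,
        table.g_dim,
        table.g_mono,
        table.csr_ptr,
        table.csr_idx,
        sample_times,
        np.uint32(kernel_seed),
        float(stop_count),
        3,
        1_000_000,
        False,
    )
    (nmc, ndc, nmo, ndo, n_events, t_final, stopped, absorbed, _, _, _) = out

    rows = []
    for k, t in enumerate(sample_times):
        rows.append((t, "central", int(nmc[k]), int(ndc[k]), int(nmc[k]) + 2 * int(ndc[k])))
        rows.append((t, "outer", int(nmo[k]), int(ndo[k]), int(nmo[k]) + 2 * int(ndo[k])))
    frame = pd.DataFrame(
        rows, columns=["time_s", "region", "n_monomer", "n_dimer", "n_receptors"]
    )
    frame["replicate"] = replicate
    frame["engine"] = engine

    # receptor conservation must hold at every sample
    tot = frame.groupby("time_s")["n_receptors"].sum()
    if not np.all(tot.to_numpy() == n_rec0):
        raise RuntimeError("receptor conservation violated in kernel run")

    meta = {
        "engine": engine,
        "replicate": replicate,
        "base_seed": base_seed,
        "kernel_seed": kernel_seed,
        "n_receptors": n_rec0,
        "n_monomer_0": n_m0,
        "n_dimer_0": n_d0,
        "realized_density_um2": n_rec0 / geom.box_area_um2,
        "n_sites": geom.n_sites,
        "n_central_sites": geom.n_central,
        "n_cells": len(table.q),
        "n_channels": len(table.ch_a),
        "n_events": int(n_events),
        "t_final": float(t_final),
        "stopped_early": bool(stopped),
        "absorbing": bool(absorbed),
        "config": scenario.to_dict(),
    }
    return Trajectory(frame=frame, meta=meta)


def simulate_replicates(
    scenario,
    engine: str = "acgmc",
    n_replicates: int = 10,
    base_seed: int = 0,
    stop_below_ratio: float | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run ``n_replicates`` independent replicates; concatenated tidy frame."""
    frames, metas = [], []
    for rep in range(n_replicates):
        traj = simulate(
            scenario,
            engine=engine,
            base_seed=base_seed,
            replicate=rep,
            stop_below_ratio=stop_below_ratio,
        )
        frames.append(traj.frame)
        metas.append(traj.meta)
    return pd.concat(frames, ignore_index=True), metas


def write_trajectory(path_csv, frame: pd.DataFrame, meta: dict | None = None) -> None:
    """Tidy CSV plus a JSON metadata sidecar (``<path>.meta.json``)."""
    import json
    from pathlib import Path

    frame.to_csv(path_csv, index=False)
    if meta is not None:
        Path(str(path_csv) + ".meta.json").write_text(json.dumps(meta, indent=2, default=str))
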