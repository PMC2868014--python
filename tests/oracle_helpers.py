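"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths they check:

* exhaustive placement enumeration for coarse-propensity expectations
  (rational arithmetic, no well-mixed closed forms);
* exhaustive master-equation construction for a tiny lattice sector
  (stationary distribution by linear algebra, no simulation).
"""

from fractions import Fraction
from itertools import combinations

import numpy as np

from corralmc.kinetics import enumerate_channels, DIMERIZE, HOP, MONOMERIZE
from corralmc.lattice import MicroState, Species


def rect_internal_edges(w: int, h: int):
    """Adjacent site pairs of an isolated w x h block (no periodic wrap)."""
    edges = []
    for r in range(h):
        for c in range(w):
            if c + 1 < w:
                edges.append(((r, c), (r, c + 1)))
            if r + 1 < h:
                edges.append(((r, c), (r + 1, c)))
    return edges


def placement_expectation(w: int, h: int, n_m: int, n_d: int, k_m, k_d):
    """Exact expected (monomerization, dimerization) propensity of one cell.

    Averages the summed microscopic propensities over every distinct placement
    of ``n_m`` monomers and ``n_d`` dimers on the ``w*h`` sites, in exact
    rational arithmetic.  Monomerization: one channel per (dimer, vacant
    in-cell neighbor) at rate k_m; dimerization: one channel per adjacent
    monomer pair at rate k_d.
    """
    q = w * h
    sites = [(r, c) for r in range(h) for c in range(w)]
    edges = rect_internal_edges(w, h)
    neigh = {s: [] for s in sites}
    for a, b in edges:
        neigh[a].append(b)
        neigh[b].append(a)

    total_mono = Fraction(0)
    total_dim = Fraction(0)
    n_placements = 0
    for d_sites in combinations(range(q), n_d):
        rest = [i for i in range(q) if i not in d_sites]
        for m_sites in combinations(rest, n_m):
            occ = {}
            for i in d_sites:
                occ[sites[i]] = "D"
            for i in m_sites:
                occ[sites[i]] = "M"
            mono = sum(
                1
                for s, v in occ.items()
                if v == "D"
                for nb in neigh[s]
                if nb not in occ
            )
            dim = sum(
                1 for a, b in edges if occ.get(a) == "M" and occ.get(b) == "M"
            )
            total_mono += mono
            total_dim += dim
            n_placements += 1
    return (
        Fraction(k_m) * total_mono / n_placements,
        Fraction(k_d) * total_dim / n_placements,
    )


def pair_placement_expectation(w, h, n_m_a, n_d_a, n_m_b, n_d_b, ell, k_m, k_d):
    """Exact expected cross-cell (mono a->b, mono b->a, dimerization) rates.

    Two independent well-mixed cells of ``w*h`` sites joined by ``ell``
    boundary bonds; each bond end is a uniformly random site of its cell, so
    per-bond occupancy probabilities are the cell marginals.
    """
    q = Fraction(w * h)
    pm_a, pd_a = Fraction(n_m_a) / q, Fraction(n_d_a) / q
    pm_b, pd_b = Fraction(n_m_b) / q, Fraction(n_d_b) / q
    pv_a = 1 - pm_a - pd_a
    pv_b = 1 - pm_b - pd_b
    return (
        Fraction(k_m) * ell * pd_a * pv_b,
        Fraction(k_m) * ell * pd_b * pv_a,
        Fraction(k_d) * ell * pm_a * pm_b,
    )


# ---------------------------------------------------------------------------
# Master-equation oracle for the 2-receptor sector of a small lattice.
# ---------------------------------------------------------------------------


def _state_key(occ):
    return tuple(occ.reshape(-1).tolist())


def enumerate_sector(state0: MicroState, rates):
    """All states reachable from ``state0`` and the generator matrix Q.

    Builds the continuous-time Markov chain exactly: dimerization channels
    split their rate half/half between the two product placements, matching
    the engines' fair-coin rule.  Returns (states, Q) with
    Q[i, j] = rate i -> j and Q[i, i] = -sum.
    """
    geom = state0.geom
    index = {}
    states = []
    frontier = [state0.occ.copy()]
    index[_state_key(state0.occ)] = 0
    states.append(state0.occ.copy())
    transitions = []
    while frontier:
        occ = frontier.pop()
        i = index[_state_key(occ)]
        st = MicroState(geom=geom, occ=occ.copy())
        for ch in enumerate_channels(st, rates):
            succs = []
            (s1, s2) = ch.sites
            if ch.kind == HOP:
                new = occ.copy()
                new[s2] = new[s1]
                new[s1] = 0
                succs.append((new, ch.propensity))
            elif ch.kind == DIMERIZE:
                for keep, free in ((s1, s2), (s2, s1)):
                    new = occ.copy()
                    new[keep] = int(Species.DIMER)
                    new[free] = 0
                    succs.append((new, ch.propensity / 2.0))
            elif ch.kind == MONOMERIZE:
                new = occ.copy()
                new[s1] = int(Species.MONOMER)
                new[s2] = int(Species.MONOMER)
                succs.append((new, ch.propensity))
            for new, rate in succs:
                key = _state_key(new)
                if key not in index:
                    index[key] = len(states)
                    states.append(new.copy())
                    frontier.append(new.copy())
                transitions.append((i, index[key], rate))
    n = len(states)
    Q = np.zeros((n, n))
    for i, j, rate in transitions:
        Q[i, j] += rate
        Q[i, i] -= rate
    return states, Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary pi with pi Q = 0, sum pi = 1 (least-squares on Q^T)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
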