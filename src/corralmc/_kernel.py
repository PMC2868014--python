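"""Compiled event loop shared by the kmc / ucgmc / acgmc engines.

The kernel executes the channel table built in :mod:`corralmc.coarse`:
channels are cell pairs (hops, cross-cell dimerization / monomerization) or
single cells (within-cell reactions); propensities are bilinear in the cell
counts with precomputed coefficients.  Selection uses a flat binary sum tree;
after an event only the channels touching the one or two modified cells are
recomputed, and the tree is rebuilt from scratch periodically to bound
floating-point drift.

Sampling semantics: each requested sample time reports the state immediately
before the first event after that time.  An absorbing state (total propensity
zero) freezes the remaining samples and is flagged; the optional early stop
triggers once the central-region receptor count has stayed below a threshold
for ``debounce`` consecutive samples (the cluster has dissipated).
"""

import numpy as np
from numba import njit


@njit(inline="always")
def _chan_prop(c, ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd):
    a = ch_a[c]
    b = ch_b[c]
    if b < 0:
        m = nm[a]
        d = nd[a]
        v = q[a] - m - d
        return g_dim[c] * m * (m - 1) + g_mono[c] * d * v
    ma = nm[a]
    da = nd[a]
    va = q[a] - ma - da
    mb = nm[b]
    db = nd[b]
    vb = q[b] - mb - db
    return (
        g_hop_m[c] * (ma * vb + mb * va)
        + g_hop_d[c] * (da * vb + db * va)
        + g_dim[c] * ma * mb
        + g_mono[c] * (da * vb + db * va)
    )


@njit(inline="always")
def _refresh_cell(
    cell, ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd, csr_ptr, csr_idx, tree, m_leaf
):
    for k in range(csr_ptr[cell], csr_ptr[cell + 1]):
        c = csr_idx[k]
        p_new = _chan_prop(c, ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd)
        i = m_leaf + c
        delta = p_new - tree[i]
        if delta != 0.0:
            while i >= 1:
                tree[i] += delta
                i //= 2


@njit(inline="always")
def _rebuild_tree(ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd, tree, m_leaf, n_ch):
    for i in range(tree.shape[0]):
        tree[i] = 0.0
    for c in range(n_ch):
        tree[m_leaf + c] = _chan_prop(c, ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd)
    for i in range(m_leaf - 1, 0, -1):
        tree[i] = tree[2 * i] + tree[2 * i + 1]


@njit
def run_kernel(
    q,
    is_central,
    nm,
    nd,
    ch_a,
    ch_b,
    g_hop_m,
    g_hop_d,
    g_dim,
    g_mono,
    csr_ptr,
    csr_idx,
    sample_times,
    seed,
    stop_count,
    debounce,
    rebuild_every,
    track_single,
):
    np.random.seed(seed)
    n_ch = ch_a.shape[0]
    n_cells = q.shape[0]
    m_leaf = 1
    while m_leaf < n_ch:
        m_leaf *= 2
    tree = np.zeros(2 * m_leaf, dtype=np.float64)
    _rebuild_tree(ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd, tree, m_leaf, n_ch)

    nmc = 0
    ndc = 0
    nmo = 0
    ndo = 0
    cur_cell = -1
    for i in range(n_cells):
        if is_central[i] != 0:
            nmc += nm[i]
            ndc += nd[i]
        else:
            nmo += nm[i]
            ndo += nd[i]
        if track_single and nm[i] + nd[i] > 0:
            cur_cell = i

    n_s = sample_times.shape[0]
    out_nmc = np.zeros(n_s, dtype=np.int64)
    out_ndc = np.zeros(n_s, dtype=np.int64)
    out_nmo = np.zeros(n_s, dtype=np.int64)
    out_ndo = np.zeros(n_s, dtype=np.int64)
    out_cell = np.full(n_s, -1, dtype=np.int64)

    t = 0.0
    s_idx = 0
    n_events = 0
    streak = 0
    stopped = 0
    absorbed = 0

    while s_idx < n_s:
        a0 = tree[1]
        if a0 <= 0.0:
            absorbed = 1
            while s_idx < n_s:
                out_nmc[s_idx] = nmc
                out_ndc[s_idx] = ndc
                out_nmo[s_idx] = nmo
                out_ndo[s_idx] = ndo
                out_cell[s_idx] = cur_cell
                s_idx += 1
            break
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        t_next = t - np.log(u) / a0

        while s_idx < n_s and sample_times[s_idx] <= t_next:
            out_nmc[s_idx] = nmc
            out_ndc[s_idx] = ndc
            out_nmo[s_idx] = nmo
            out_ndo[s_idx] = ndo
            out_cell[s_idx] = cur_cell
            if stop_count >= 0.0:
                if nmc + 2 * ndc < stop_count:
                    streak += 1
                else:
                    streak = 0
                if streak >= debounce:
                    stopped = 1
            s_idx += 1
        if stopped == 1:
            while s_idx < n_s:
                out_nmc[s_idx] = nmc
                out_ndc[s_idx] = ndc
                out_nmo[s_idx] = nmo
                out_ndo[s_idx] = ndo
                out_cell[s_idx] = cur_cell
                s_idx += 1
            break
        if s_idx >= n_s:
            t = sample_times[n_s - 1]
            break
        t = t_next

        # --- select channel ---
        r = np.random.random() * a0
        i = 1
        while i < m_leaf:
            i *= 2
            if r >= tree[i]:
                r -= tree[i]
                i += 1
        c = i - m_leaf
        if c >= n_ch:
            c = n_ch - 1
            r = 0.0

        a = ch_a[c]
        b = ch_b[c]
        ia = is_central[a]
        if b < 0:
            # intra-cell reaction: dimerization then monomerization
            m_a = nm[a]
            d_a = nd[a]
            v_a = q[a] - m_a - d_a
            p_dim = g_dim[c] * m_a * (m_a - 1)
            if r < p_dim and p_dim > 0.0:
                nm[a] -= 2
                nd[a] += 1
                if ia != 0:
                    nmc -= 2
                    ndc += 1
                else:
                    nmo -= 2
                    ndo += 1
            else:
                nd[a] -= 1
                nm[a] += 2
                if ia != 0:
                    ndc -= 1
                    nmc += 2
                else:
                    ndo -= 1
                    nmo += 2
            _refresh_cell(a, ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd, csr_ptr, csr_idx, tree, m_leaf)
        else:
            ib = is_central[b]
            m_a = nm[a]
            d_a = nd[a]
            v_a = q[a] - m_a - d_a
            m_b = nm[b]
            d_b = nd[b]
            v_b = q[b] - m_b - d_b
            t1 = g_hop_m[c] * m_a * v_b  # M hop a->b
            t2 = g_hop_m[c] * m_b * v_a  # M hop b->a
            t3 = g_hop_d[c] * d_a * v_b  # D hop a->b
            t4 = g_hop_d[c] * d_b * v_a  # D hop b->a
            t5 = g_dim[c] * m_a * m_b  # cross dimerization
            t6 = g_mono[c] * d_a * v_b  # dissociation a, monomer lands in b
            # t7 (dissociation b -> a) is the remainder
            if r < t1:
                nm[a] -= 1
                nm[b] += 1
                nmc += ib - ia
                nmo += ia - ib
                if track_single:
                    cur_cell = b
            elif r < t1 + t2:
                nm[b] -= 1
                nm[a] += 1
                nmc += ia - ib
                nmo += ib - ia
                if track_single:
                    cur_cell = a
            elif r < t1 + t2 + t3:
                nd[a] -= 1
                nd[b] += 1
                ndc += ib - ia
                ndo += ia - ib
                if track_single:
                    cur_cell = b
            elif r < t1 + t2 + t3 + t4:
                nd[b] -= 1
                nd[a] += 1
                ndc += ia - ib
                ndo += ib - ia
                if track_single:
                    cur_cell = a
            elif r < t1 + t2 + t3 + t4 + t5:
                # cross-cell dimerization; fair coin for product placement
                nm[a] -= 1
                nm[b] -= 1
                nmc -= ia + ib
                nmo -= 2 - ia - ib
                if np.random.random() < 0.5:
                    nd[a] += 1
                    ndc += ia
                    ndo += 1 - ia
                else:
                    nd[b] += 1
                    ndc += ib
                    ndo += 1 - ib
            elif r < t1 + t2 + t3 + t4 + t5 + t6:
                nd[a] -= 1
                nm[a] += 1
                nm[b] += 1
                ndc -= ia
                ndo -= 1 - ia
                nmc += ia + ib
                nmo += 2 - ia - ib
            else:
                nd[b] -= 1
                nm[b] += 1
                nm[a] += 1
                ndc -= ib
                ndo -= 1 - ib
                nmc += ia + ib
                nmo += 2 - ia - ib
            _refresh_cell(a, ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd, csr_ptr, csr_idx, tree, m_leaf)
            _refresh_cell(b, ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd, csr_ptr, csr_idx, tree, m_leaf)

        n_events += 1
        if n_events % rebuild_every == 0:
            _rebuild_tree(ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd, tree, m_leaf, n_ch)

    return (
        out_nmc,
        out_ndc,
        out_nmo,
        out_ndo,
        n_events,
        t,
        stopped,
        absorbed,
        nm,
        nd,
        out_cell,
    )


@njit
def run_kernel_hist(
    q,
    nm,
    nd,
    ch_a,
    ch_b,
    g_hop_m,
    g_hop_d,
    g_dim,
    g_mono,
    csr_ptr,
    csr_idx,
    seed,
    n_events_max,
):
    """Time-weighted occupancy histogram over encoded microstates.

    Requires all cells to be single sites (q = 1, at most 12 cells): the state
    code is ``sum_i s_i 3^i`` with s_i in {0 vacant, 1 monomer, 2 dimer}.
    Used by the master-equation stationarity oracle.
    """
    np.random.seed(seed)
    n_ch = ch_a.shape[0]
    n_cells = q.shape[0]
    m_leaf = 1
    while m_leaf < n_ch:
        m_leaf *= 2
    tree = np.zeros(2 * m_leaf, dtype=np.float64)
    _rebuild_tree(ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd, tree, m_leaf, n_ch)

    pow3 = np.ones(n_cells, dtype=np.int64)
    for i in range(1, n_cells):
        pow3[i] = pow3[i - 1] * 3
    hist = np.zeros(pow3[n_cells - 1] * 3, dtype=np.float64)

    code = 0
    for i in range(n_cells):
        code += (nm[i] + 2 * nd[i]) * pow3[i]

    n_events = 0
    while n_events < n_events_max:
        a0 = tree[1]
        if a0 <= 0.0:
            break
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        tau = -np.log(u) / a0
        hist[code] += tau

        r = np.random.random() * a0
        i = 1
        while i < m_leaf:
            i *= 2
            if r >= tree[i]:
                r -= tree[i]
                i += 1
        c = i - m_leaf
        if c >= n_ch:
            c = n_ch - 1
            r = 0.0
        a = ch_a[c]
        b = ch_b[c]
        m_a = nm[a]
        d_a = nd[a]
        v_a = q[a] - m_a - d_a
        m_b = nm[b]
        d_b = nd[b]
        v_b = q[b] - m_b - d_b
        t1 = g_hop_m[c] * m_a * v_b
        t2 = g_hop_m[c] * m_b * v_a
        t3 = g_hop_d[c] * d_a * v_b
        t4 = g_hop_d[c] * d_b * v_a
        t5 = g_dim[c] * m_a * m_b
        t6 = g_mono[c] * d_a * v_b
        if r < t1:
            nm[a] -= 1
            nm[b] += 1
            code += pow3[b] - pow3[a]
        elif r < t1 + t2:
            nm[b] -= 1
            nm[a] += 1
            code += pow3[a] - pow3[b]
        elif r < t1 + t2 + t3:
            nd[a] -= 1
            nd[b] += 1
            code += 2 * (pow3[b] - pow3[a])
        elif r < t1 + t2 + t3 + t4:
            nd[b] -= 1
            nd[a] += 1
            code += 2 * (pow3[a] - pow3[b])
        elif r < t1 + t2 + t3 + t4 + t5:
            nm[a] -= 1
            nm[b] -= 1
            if np.random.random() < 0.5:
                nd[a] += 1
                code += pow3[a] - pow3[b]
            else:
                nd[b] += 1
                code += pow3[b] - pow3[a]
        elif r < t1 + t2 + t3 + t4 + t5 + t6:
            nd[a] -= 1
            nm[a] += 1
            nm[b] += 1
            code += pow3[b] - pow3[a]
        else:
            nd[b] -= 1
            nm[b] += 1
            nm[a] += 1
            code += pow3[a] - pow3[b]
        _refresh_cell(a, ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd, csr_ptr, csr_idx, tree, m_leaf)
        _refresh_cell(b, ch_a, ch_b, g_hop_m, g_hop_d, g_dim, g_mono, q, nm, nd, csr_ptr, csr_idx, tree, m_leaf)
        n_events += 1
    return hist, n_events
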