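"""Event-driven structured-coalescent kernel (numba-jitted).

Time runs backward in continuous generations.  A compiled demography is a
piecewise-constant description over intervals ``[bounds[i], bounds[i+1])``:
per-interval population sizes ``N0`` (diploid, at interval start) with
within-interval exponential decay rates ``G`` (so the size ``dt`` into the
interval is ``N0*exp(-G*dt)``, the backward image of forward exponential
growth), a backward migration matrix ``MB`` (``MB[i, p, q]`` = rate at which
a lineage in ``p`` moves to ``q``), and population merges applied on entry
to an interval.

Within an interval the next event is drawn as an exact exponential race:
coalescence candidates per population use the closed-form inverse of the
time-inhomogeneous hazard ``C/(2 N(t))`` under exponential size change, and
migration is homogeneous.  Candidates beyond the interval end are discarded
and redrawn in the next interval, which is exact because the processes are
(conditionally) memoryless.
"""

import numpy as np
from numba import njit

# status codes returned by _simulate_tree
OK = 0
EVENT_CAP_EXCEEDED = 1

_MAX_EVENTS = 1_000_000


@njit(cache=True)
def _simulate_tree(seed, lin_pop0, bounds, N0, G, MB, MIGOUT,
                   merge_iv, merge_from, merge_to, parent, times, node_pop):
    """Simulate one genealogy; fill parent/times/node_pop arrays.

    parent, times, node_pop must have length 2n-1; leaves are nodes 0..n-1.
    Returns a status code.
    """
    np.random.seed(seed)
    n = lin_pop0.shape[0]
    P = N0.shape[1]
    n_int = bounds.shape[0]

    # active lineage slots
    lin_node = np.empty(2 * n - 1, np.int64)
    lin_pop = np.empty(2 * n - 1, np.int64)
    for i in range(n):
        lin_node[i] = i
        lin_pop[i] = lin_pop0[i]
        parent[i] = -1
        times[i] = 0.0
        node_pop[i] = lin_pop0[i]
    n_active = n
    next_node = n
    k_pop = np.zeros(P, np.int64)
    for i in range(n):
        k_pop[lin_pop0[i]] += 1

    t = 0.0
    iv = 0
    n_merges = merge_iv.shape[0]
    events = 0

    while n_active > 1:
        events += 1
        if events > _MAX_EVENTS:
            return EVENT_CAP_EXCEEDED
        t_end = bounds[iv + 1] if iv + 1 < n_int else np.inf

        # candidate coalescence per population (closed form under decay)
        best_dt = np.inf
        best_kind = -1  # 0 coal, 1 migration
        best_pop = -1
        for p in range(P):
            k = k_pop[p]
            if k < 2:
                continue
            C = 0.5 * k * (k - 1)
            Np = N0[iv, p] * np.exp(-G[iv, p] * (t - bounds[iv]))
            lam0 = C / (2.0 * Np)
            E = np.random.exponential(1.0)
            g = G[iv, p]
            if g == 0.0:
                dt = E / lam0
            else:
                dt = np.log(1.0 + g * E / lam0) / g
            if dt < best_dt:
                best_dt = dt
                best_kind = 0
                best_pop = p

        # candidate migration (homogeneous within interval)
        rtot = 0.0
        for p in range(P):
            rtot += k_pop[p] * MIGOUT[iv, p]
        if rtot > 0.0:
            dt = np.random.exponential(1.0) / rtot
            if dt < best_dt:
                best_dt = dt
                best_kind = 1

        if t + best_dt >= t_end:
            # cross into the next interval; apply merges scheduled there
            t = t_end
            iv += 1
            for m in range(n_merges):
                if merge_iv[m] == iv:
                    src = merge_from[m]
                    dst = merge_to[m]
                    for s in range(n_active):
                        if lin_pop[s] == src:
                            lin_pop[s] = dst
                    k_pop[dst] += k_pop[src]
                    k_pop[src] = 0
            continue

        t = t + best_dt
        if best_kind == 0:
            # coalescence in best_pop: draw an unordered pair uniformly
            k = k_pop[best_pop]
            r1 = np.random.randint(0, k)
            r2 = np.random.randint(0, k - 1)
            if r2 >= r1:
                r2 += 1
            s1 = -1
            s2 = -1
            c = 0
            for s in range(n_active):
                if lin_pop[s] == best_pop:
                    if c == r1:
                        s1 = s
                    if c == r2:
                        s2 = s
                    c += 1
            node = next_node
            next_node += 1
            times[node] = t
            node_pop[node] = best_pop
            parent[node] = -1
            parent[lin_node[s1]] = node
            parent[lin_node[s2]] = node
            # replace slot s1 with the new lineage, drop slot s2
            lin_node[s1] = node
            if s2 != n_active - 1:
                lin_node[s2] = lin_node[n_active - 1]
                lin_pop[s2] = lin_pop[n_active - 1]
            n_active -= 1
            k_pop[best_pop] -= 1
        else:
            # migration: pick lineage weighted by its population's out-rate
            r = np.random.random() * rtot
            acc = 0.0
            chosen = -1
            for s in range(n_active):
                acc += MIGOUT[iv, lin_pop[s]]
                if acc >= r:
                    chosen = s
                    break
            if chosen < 0:
                chosen = n_active - 1
            p = lin_pop[chosen]
            r2 = np.random.random() * MIGOUT[iv, p]
            acc = 0.0
            dest = -1
            for q in range(P):
                acc += MB[iv, p, q]
                if acc >= r2:
                    dest = q
                    break
            if dest < 0:
                for q in range(P - 1, -1, -1):
                    if MB[iv, p, q] > 0.0:
                        dest = q
                        break
            k_pop[p] -= 1
            k_pop[dest] += 1
            lin_pop[chosen] = dest
    return OK


@njit(cache=True)
def _descendant_counts(parent, leaf_pops, P, counts):
    """Per-node leaf counts per population; nodes are in creation order so a
    parent always has a higher index than its children."""
    n_nodes = parent.shape[0]
    n = (n_nodes + 1) // 2
    counts[:] = 0
    for v in range(n):
        counts[v, leaf_pops[v]] = 1
    for v in range(n_nodes - 1):
        pa = parent[v]
        if pa >= 0:
            for p in range(P):
                counts[pa, p] += counts[v, p]


@njit(cache=True)
def _batch_pair_sfs(seeds, lin_pop0, bounds, N0, G, MB, MIGOUT,
                    merge_iv, merge_from, merge_to,
                    pair_a, pair_b, nhap_a, nhap_b,
                    fold_flat, fold_off, out_off, out_flat,
                    poisson_mode, theta):
    """Simulate a batch of independent loci and accumulate folded joint-SFS
    contributions for every population pair.

    In branch mode each branch contributes its length (in generations) to
    the folded cell determined by its descendant counts; normalising the
    result estimates the per-polymorphic-site cell probabilities.  In
    Poisson mode each branch carries ``Poisson(theta * len)`` mutations; a
    single draw per branch is shared by all pairs, so the six pairwise
    spectra describe the same underlying sites.  Returns the status of the
    worst locus.
    """
    n = lin_pop0.shape[0]
    P = N0.shape[1]
    n_nodes = 2 * n - 1
    n_pairs = pair_a.shape[0]
    parent = np.empty(n_nodes, np.int64)
    times = np.empty(n_nodes, np.float64)
    node_pop = np.empty(n_nodes, np.int64)
    counts = np.zeros((n_nodes, P), np.int64)
    worst = OK
    for l in range(seeds.shape[0]):
        status = _simulate_tree(seeds[l], lin_pop0, bounds, N0, G, MB, MIGOUT,
                                merge_iv, merge_from, merge_to,
                                parent, times, node_pop)
        if status != OK:
            worst = status
            continue
        _descendant_counts(parent, lin_pop0, P, counts)
        for v in range(n_nodes - 1):
            pa = parent[v]
            if pa < 0:
                continue
            blen = times[pa] - times[v]
            if blen <= 0.0:
                continue
            if poisson_mode:
                kmut = np.random.poisson(theta * blen)
                if kmut == 0:
                    continue
                w = float(kmut)
            else:
                w = blen
            for pr in range(n_pairs):
                i = counts[v, pair_a[pr]]
                j = counts[v, pair_b[pr]]
                idx = i * (nhap_b[pr] + 1) + j
                cell = fold_flat[fold_off[pr] + idx]
                if cell >= 0:
                    out_flat[out_off[pr] + cell] += w
    return worst
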