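"""Numba kernel for the per-locus Kingman coalescent with demographic events.

Each locus is an independent realisation: lineages coalesce within a
population of diploid size N at rate k(k-1)/(4N) per generation
(continuous time), demographic events are applied backward in time at their
scheduled generations, and exactly one mutation is placed uniformly at
random on the total branch length, yielding a biallelic SNP that is
polymorphic in the pooled sample by construction.

Event encoding (parallel arrays, ascending time):
  kind 0  merge:       move all lineages of pop a into pop b
  kind 1  admixture:   each lineage of pop a moves to pop b with prob x,
                       otherwise to pop c (c == a means "stay")
  kind 2  size change: set N[a] = x
"""

from __future__ import annotations

import numpy as np
from numba import njit

EV_MERGE = 0
EV_ADMIX = 1
EV_SIZE = 2


@njit(cache=True)
def simulate_loci(
    seeds,          # uint32[n_loci] per-locus RNG seeds
    lin0,           # int64[n_pops] initial lineage counts (2 x diploids)
    size0,          # float64[n_pops] initial diploid sizes
    ev_time,        # float64[n_ev] ascending event times (generations)
    ev_kind,        # int64[n_ev]
    ev_a,           # int64[n_ev]
    ev_b,           # int64[n_ev]
    ev_c,           # int64[n_ev]
    ev_x,           # float64[n_ev]
    derived,        # uint8[n_loci, n_tips] output: derived-allele indicator
    tmrca,          # float64[n_loci] output: tree height (generations)
):
    n_loci = seeds.shape[0]
    n_pops = lin0.shape[0]
    n_ev = ev_time.shape[0]
    n_tips = 0
    for p in range(n_pops):
        n_tips += lin0[p]
    n_nodes = 2 * n_tips - 1

    member = np.empty((n_pops, n_tips), dtype=np.int64)
    cnt = np.empty(n_pops, dtype=np.int64)
    sizes = np.empty(n_pops, dtype=np.float64)
    node_time = np.empty(n_nodes, dtype=np.float64)
    parent = np.empty(n_nodes, dtype=np.int64)
    child1 = np.empty(n_nodes, dtype=np.int64)
    child2 = np.empty(n_nodes, dtype=np.int64)
    stack = np.empty(n_nodes, dtype=np.int64)

    for locus in range(n_loci):
        np.random.seed(seeds[locus])
        # reset state
        tip = 0
        for p in range(n_pops):
            cnt[p] = lin0[p]
            sizes[p] = size0[p]
            for i in range(lin0[p]):
                member[p, i] = tip
                tip += 1
        for i in range(n_nodes):
            node_time[i] = 0.0
            parent[i] = -1
            child1[i] = -1
            child2[i] = -1

        t = 0.0
        ev_i = 0
        n_active = n_tips
        next_node = n_tips
        while n_active > 1:
            total_rate = 0.0
            for p in range(n_pops):
                k = cnt[p]
                if k > 1:
                    total_rate += k * (k - 1.0) / (4.0 * sizes[p])
            next_ev = ev_time[ev_i] if ev_i < n_ev else np.inf
            if total_rate > 0.0:
                dt = np.random.exponential(1.0 / total_rate)
            else:
                dt = np.inf
                if ev_i >= n_ev:
                    raise ValueError("lineages cannot coalesce: scenario never joins all populations")
            if t + dt < next_ev:
                t += dt
                # choose population proportional to its coalescence rate
                u = np.random.random() * total_rate
                acc = 0.0
                chosen = -1
                for p in range(n_pops):
                    k = cnt[p]
                    if k > 1:
                        acc += k * (k - 1.0) / (4.0 * sizes[p])
                        if u <= acc:
                            chosen = p
                            break
                if chosen < 0:  # numerical guard
                    for p in range(n_pops):
                        if cnt[p] > 1:
                            chosen = p
                            break
                k = cnt[chosen]
                i = np.random.randint(0, k)
                j = np.random.randint(0, k - 1)
                if j >= i:
                    j += 1
                a = member[chosen, i]
                b = member[chosen, j]
                node = next_node
                next_node += 1
                node_time[node] = t
                child1[node] = a
                child2[node] = b
                parent[a] = node
                parent[b] = node
                # replace slot i with the new node, move last lineage into slot j
                lo = i if i < j else j
                hi = j if i < j else i
                member[chosen, lo] = node
                member[chosen, hi] = member[chosen, k - 1]
                cnt[chosen] = k - 1
                n_active -= 1
            else:
                t = next_ev
                kind = ev_kind[ev_i]
                a_p = ev_a[ev_i]
                if kind == EV_MERGE:
                    b_p = ev_b[ev_i]
                    for i in range(cnt[a_p]):
                        member[b_p, cnt[b_p] + i] = member[a_p, i]
                    cnt[b_p] += cnt[a_p]
                    cnt[a_p] = 0
                elif kind == EV_ADMIX:
                    b_p = ev_b[ev_i]
                    c_p = ev_c[ev_i]
                    x = ev_x[ev_i]
                    keep = 0
                    for i in range(cnt[a_p]):
                        lin = member[a_p, i]
                        dest = b_p if np.random.random() < x else c_p
                        if dest == a_p:
                            member[a_p, keep] = lin
                            keep += 1
                        else:
                            member[dest, cnt[dest]] = lin
                            cnt[dest] += 1
                    cnt[a_p] = keep
                else:  # EV_SIZE
                    sizes[a_p] = ev_x[ev_i]
                ev_i += 1
        root = next_node - 1
        tmrca[locus] = node_time[root]

        # place one mutation uniformly on the total branch length
        total_len = 0.0
        for v in range(root):
            total_len += node_time[parent[v]] - node_time[v]
        u = np.random.random() * total_len
        acc = 0.0
        mut = 0
        for v in range(root):
            acc += node_time[parent[v]] - node_time[v]
            if u <= acc:
                mut = v
                break
        # mark tips below the mutated branch
        for s in range(n_tips):
            derived[locus, s] = 0
        top = 0
        stack[top] = mut
        top += 1
        while top > 0:
            top -= 1
            v = stack[top]
            if v < n_tips:
                derived[locus, v] = 1
            else:
                stack[top] = child1[v]
                top += 1
                stack[top] = child2[v]
                top += 1
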