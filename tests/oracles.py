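"""Brute-force reference implementations used only to cross-check results.

These deliberately avoid networkx and the package's own algorithms: cliques
by subset enumeration, betweenness by explicit shortest-path enumeration,
biconnected components by per-vertex-removal connectivity checks over all
subsets, and the power-law exponent by grid-search likelihood maximization.
Everything is written for tiny graphs (n <= 12) with bitmask arithmetic.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special


def _adj_masks(nodes, edges):
    idx = {u: i for i, u in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    return idx, adj


def _connected(subset: int, adj) -> bool:
    if subset == 0:
        return True
    start = subset & -subset
    seen = start
    frontier = start
    while frontier:
        nxt = 0
        m = frontier
        while m:
            b = m & -m
            nxt |= adj[b.bit_length() - 1]
            m ^= b
        nxt &= subset & ~seen
        seen |= nxt
        frontier = nxt
    return seen == subset


def brute_force_maximal_cliques(nodes, edges):
    """All maximal cliques by testing every one of the 2^n subsets."""
    nodes = list(nodes)
    idx, adj = _adj_masks(nodes, edges)
    n = len(nodes)
    cliques = []
    for s in range(1, 1 << n):
        ok = True
        m = s
        while m:
            b = m & -m
            i = b.bit_length() - 1
            if (adj[i] & s) != (s & ~b):
                ok = False
                break
            m ^= b
        if ok:
            cliques.append(s)
    maximal = [
        c for c in cliques if not any(c != d and (c & d) == c for d in cliques)
    ]
    out = []
    for c in maximal:
        out.append(sorted(nodes[i] for i in range(n) if c >> i & 1))
    out.sort(key=lambda c: (-len(c), c))
    return out


def brute_force_betweenness(nodes, edges):
    """Unnormalized betweenness via explicit enumeration of shortest paths."""
    nodes = list(nodes)
    idx, adj_mask = _adj_masks(nodes, edges)
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_shortest_paths(s, t):
        # BFS distance first, then DFS enumerating every geodesic
        dist = {s: 0}
        frontier = [s]
        while frontier and t not in dist:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def dfs(u, path):
            if u == t:
                paths.append(list(path))
                return
            for w in adj[u]:
                if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                    path.append(w)
                    dfs(w, path)
                    path.pop()

        dfs(s, [s])
        return paths

    bc = {u: 0.0 for u in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for p in paths:
                for u in p[1:-1]:
                    bc[u] += 1.0 / len(paths)
    return bc


def brute_force_biconnected_sets(nodes, edges):
    """Vertex sets of the biconnected components, by subset enumeration.

    A subset qualifies when its induced subgraph is connected, stays
    connected after removal of any single vertex (pairs must simply be an
    edge), and is maximal among qualifying subsets.
    """
    nodes = list(nodes)
    idx, adj = _adj_masks(nodes, edges)
    n = len(nodes)
    good = []
    for s in range(1, 1 << n):
        k = s.bit_count()
        if k < 2:
            continue
        sub_adj = [adj[i] & s for i in range(n)]
        if k == 2:
            bits = [i for i in range(n) if s >> i & 1]
            if adj[bits[0]] >> bits[1] & 1:
                good.append(s)
            continue
        if not _connected(s, sub_adj):
            continue
        ok = True
        m = s
        while m:
            b = m & -m
            if not _connected(s & ~b, sub_adj):
                ok = False
                break
            m ^= b
        if ok:
            good.append(s)
    maximal = [c for c in good if not any(c != d and (c & d) == c for d in good)]
    out = []
    for c in maximal:
        out.append(sorted(nodes[i] for i in range(n) if c >> i & 1))
    out.sort(key=lambda c: (-len(c), c))
    return out


def grid_search_alpha(sample, xmin: int, lo=1.01, hi=4.0, step=0.01) -> float:
    """Discrete power-law exponent by direct likelihood grid search."""
    tail = np.asarray([x for x in sample if x >= xmin], dtype=float)
    slogx = np.log(tail).sum()
    best_alpha, best_ll = None, -math.inf
    for alpha in np.arange(lo, hi + step / 2, step):
        ll = -tail.size * math.log(special.zeta(alpha, xmin)) - alpha * slogx
        if ll > best_ll:
            best_alpha, best_ll = float(alpha), ll
    return best_alpha
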