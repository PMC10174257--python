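"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive — BFS by hand, exhaustive
enumeration, high-precision flow simulation — and shares no code with the
package's own computational paths.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# -- topology ---------------------------------------------------------------

def bfs_distances(adj: dict, start) -> dict:
    dist = {start: 0}
    q = deque([start])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def topology_by_brute_force(nodes: list, edges: list[tuple]) -> dict:
    """All-pairs-BFS / triple-enumeration topology suite.

    ``edges`` are undirected simple pairs (no self-loops, no duplicates).
    """
    nodes = list(nodes)
    n = len(nodes)
    adj: dict = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    m = len(edges)

    # components by flood fill
    components = []
    seen: set = set()
    for v in nodes:
        if v not in seen:
            comp = set(bfs_distances(adj, v))
            components.append(comp)
            seen |= comp

    path_sum = 0
    path_pairs = 0
    ecc: dict = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        reach = [d for u, d in dist.items() if u != v]
        ecc[v] = max(reach) if reach else 0
        path_sum += sum(reach)
        path_pairs += len(reach)
    diameter = max(ecc.values()) if nodes else 0
    largest = max(components, key=len)
    radius = min(ecc[v] for v in largest) if len(largest) > 1 else 0
    cpl = path_sum / path_pairs if path_pairs else 0.0

    clustering_sum = 0.0
    for v in nodes:
        nbrs = sorted(adj[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        clustering_sum += 2.0 * links / (k * (k - 1))

    return {
        "n_nodes": n,
        "n_edges": m,
        "avg_neighbors": 2.0 * m / n if n else 0.0,
        "diameter": diameter,
        "radius": radius,
        "characteristic_path_length": cpl,
        "clustering_coefficient": clustering_sum / n if n else 0.0,
        "density": 2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
        "n_connected_components": len(components),
        "degree_distribution": dict(
            zip(*np.unique([len(adj[v]) for v in nodes], return_counts=True))),
    }


# -- hypergeometric ---------------------------------------------------------

def hypergeom_upper_tail_by_enumeration(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by enumerating every size-n draw from an N-element universe.

    The first K universe elements are the 'annotated' ones.
    """
    universe = range(N)
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total if total else 1.0


def bh_stepup_by_brute_force(pvalues: list[float], alpha: float) -> list[bool]:
    """Benjamini–Hochberg step-up applied literally to a p-value list."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if pvalues[i] <= rank * alpha / m:
            k_star = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            reject[i] = True
    return reject


def bh_qvalues_by_brute_force(pvalues: list[float]) -> list[float]:
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * m / rank)
        q[i] = running_min
    return q


# -- MCL flow simulation ----------------------------------------------------

def mcl_flow_oracle(nodes: list, edges: list[tuple], inflation: float = 3.0,
                    expansion: int = 2, self_loop: float = 1.0,
                    max_iter: int = 300, tol: float = 1e-12):
    """High-precision MCL flow simulation without pruning.

    Returns the partition as a frozenset of frozensets, using the same
    published attractor-system reading (attractor rows merged on shared
    support; overlaps to the largest system, ties to the system with the
    lexicographically smallest member) but arrived at independently: no
    pruning, a much tighter tolerance, and loop-based normalisation.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v in edges:
        if u == v:
            continue
        m[index[u], index[v]] = 1.0
        m[index[v], index[u]] = 1.0
    for i in range(n):
        m[i, i] = self_loop
    for j in range(n):
        m[:, j] /= m[:, j].sum()
    for _ in range(max_iter):
        new = m.copy()
        for _ in range(expansion - 1):
            new = new @ m
        new = new ** inflation
        for j in range(n):
            s = new[:, j].sum()
            if s > 0:
                new[:, j] /= s
        if np.abs(new - m).max() < tol:
            m = new
            break
        m = new
    eps = 1e-9
    attractors = [i for i in range(n) if m[i, i] > eps]
    support = {a: set(np.nonzero(m[a] > eps)[0]) | {a} for a in attractors}
    # merge attractor systems that share an attractor; systems sharing only
    # non-attractor nodes stay separate (their overlap is resolved below)
    attractor_set = set(attractors)
    systems: list[set] = []
    for a in attractors:
        merged = {a} | support[a]
        keep = []
        for sys_ in systems:
            if sys_ & merged & attractor_set:
                merged |= sys_
            else:
                keep.append(sys_)
        keep.append(merged)
        systems = keep
    order = sorted(range(len(systems)),
                   key=lambda i: (-len(systems[i]),
                                  min(nodes[j] for j in systems[i])))
    assigned: set = set()
    clusters = []
    for i in order:
        members = systems[i] - assigned
        if members:
            clusters.append(members)
            assigned |= members
    for j in range(n):
        if j not in assigned:
            flows = [sum(m[i, j] for i in cl) for cl in clusters]
            if flows and max(flows) > eps:
                clusters[int(np.argmax(flows))].add(j)
            else:
                clusters.append({j})
            assigned.add(j)
    return frozenset(frozenset(nodes[i] for i in cl) for cl in clusters)
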