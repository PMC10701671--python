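"""Independent brute-force oracles used to validate the library.

These deliberately avoid the code paths (and where possible the libraries)
they check: Spearman via explicit sort-based midranks and covariance sums,
edge betweenness via exhaustive BFS path enumeration, and Girvan-Newman via
a naive re-implementation built on that enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def midranks(values) -> list[float]:
    """Average ranks computed by sorting, with midranks for ties."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> tuple[float, float]:
    """(rho, p) from explicit midranks + the covariance formula + t-approx."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    rho = cov / math.sqrt(vx * vy)
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, 2.0 * stats.t.sf(abs(t), n - 2)


# ---------------------------------------------------------------------------
# graphs: adjacency as dict[node] -> set[node]
# ---------------------------------------------------------------------------


def adjacency(edges) -> dict:
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def all_shortest_paths(adj: dict, source, target) -> list[list]:
    """Every shortest path from source to target, by BFS + backtracking."""
    dist = {source: 0}
    preds: dict = {source: []}
    frontier = [source]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in adj.get(node, ()):
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    preds[nb] = [node]
                    nxt.append(nb)
                elif dist[nb] == dist[node] + 1:
                    preds[nb].append(node)
        frontier = nxt
    if target not in dist:
        return []

    paths: list[list] = []

    def backtrack(node, suffix):
        if node == source:
            paths.append([source] + suffix)
            return
        for pred in preds[node]:
            backtrack(pred, [node] + suffix)

    backtrack(target, [])
    return paths


def edge_betweenness_oracle(edges) -> dict:
    """Edge betweenness by exhaustive enumeration of all shortest paths,
    fractional credit when a pair has several."""
    adj = adjacency(edges)
    nodes = sorted(adj, key=str)
    eb = {tuple(sorted(e, key=str)): 0.0 for e in edges}
    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        credit = 1.0 / len(paths)
        for path in paths:
            for u, v in zip(path, path[1:]):
                eb[tuple(sorted((u, v), key=str))] += credit
    return eb


def components(adj: dict, nodes) -> frozenset:
    seen: set = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            for nb in adj.get(stack.pop(), ()):
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        comps.append(frozenset(comp))
    return frozenset(comps)


def modularity_oracle(edges, partition) -> float:
    """Q = sum_c (e_c/m - (d_c/2m)^2) by direct counting."""
    m = len(edges)
    degree: dict = {}
    for u, v in edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    q = 0.0
    for comm in partition:
        e_c = sum(1 for u, v in edges if u in comm and v in comm)
        d_c = sum(degree.get(n, 0) for n in comm)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def naive_girvan_newman(edges) -> tuple[float, frozenset]:
    """Independent GN: remove highest-betweenness edges (ties -> smallest
    (u, v)), recording every partition, and return (best Q, best partition)
    by exhaustive search over the recorded sequence."""
    edges = [tuple(sorted(e, key=str)) for e in edges]
    nodes = sorted({n for e in edges for n in e}, key=str)
    remaining = list(edges)
    partitions = [components(adjacency(remaining), nodes)]
    while remaining:
        eb = edge_betweenness_oracle(remaining)
        best_edge = min(eb, key=lambda e: (-round(eb[e], 10), str(e[0]), str(e[1])))
        remaining = [e for e in remaining if e != best_edge]
        partitions.append(components(adjacency(remaining), nodes))
    best_q, best_partition = -np.inf, None
    for idx, partition in enumerate(partitions):
        q = round(modularity_oracle(edges, partition), 12)
        key = (-q, len(partition), idx)
        if best_partition is None or key < best_key:
            best_q, best_partition, best_key = q, partition, key
    return best_q, best_partition


def random_connected_graph(rng: np.random.Generator, max_nodes: int):
    """Random connected labelled graph with 3..max_nodes nodes."""
    while True:
        n = int(rng.integers(3, max_nodes + 1))
        nodes = [f"n{i}" for i in range(n)]
        p = float(rng.uniform(0.3, 0.8))
        edges = [(u, v) for u, v in combinations(nodes, 2) if rng.random() < p]
        if not edges:
            continue
        if len(components(adjacency(edges), sorted({x for e in edges for x in e}))) == 1 and len(
            {x for e in edges for x in e}
        ) == n:
            return edges
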