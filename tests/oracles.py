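"""Independent brute-force oracles for nodal graph measures.

Everything here is deliberately naive — hand-rolled BFS, exhaustive
shortest-path enumeration, per-node loops — so the fast implementations can
be checked against code that shares nothing with them.
"""

from __future__ import annotations

import itertools

import numpy as np


def edges_of(adj: np.ndarray) -> list[tuple[int, int]]:
    n = adj.shape[0]
    return [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]]


def oracle_degree(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    counts = np.zeros(n, dtype=int)
    for i, j in edges_of(adj):
        counts[i] += 1
        counts[j] += 1
    return counts


def _bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, -1)
    dist[source] = 0
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Every geodesic from s to t by depth-first enumeration."""
    dist = _bfs_distances(adj, s)
    if dist[t] < 0:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in range(adj.shape[0]):
            if adj[u, v] and dist[v] == dist[u] + 1 and dist[v] <= dist[t]:
                extend(path + [v])

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


def oracle_closeness(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        dist = _bfs_distances(adj, v)
        reachable = [dist[u] for u in range(n) if u != v and dist[u] >= 0]
        r = len(reachable)
        total = sum(reachable)
        if r == 0 or total == 0:
            out[v] = 0.0
        else:
            out[v] = (r / (n - 1)) * (r / total)
    return out


def oracle_participation(adj: np.ndarray, partition: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        k = int(adj[v].sum())
        if k == 0:
            continue
        acc = 0.0
        for s in set(partition.tolist()):
            k_vs = sum(1 for u in range(n) if adj[v, u] and partition[u] == s)
            acc += (k_vs / k) ** 2
        out[v] = 1.0 - acc
    return out


def oracle_within_module_degree(adj: np.ndarray, partition: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    kappa = np.array(
        [sum(1 for u in range(n) if adj[v, u] and partition[u] == partition[v]) for v in range(n)],
        dtype=float,
    )
    out = np.zeros(n)
    for s in set(partition.tolist()):
        members = [v for v in range(n) if partition[v] == s]
        vals = kappa[members]
        sd = vals.std()  # population SD
        if sd > 0:
            for v in members:
                out[v] = (kappa[v] - vals.mean()) / sd
    return out


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    upper = np.triu(rng.random((n, n)) < p, k=1).astype(float)
    return upper + upper.T


def random_partition(n: int, n_modules: int, rng: np.random.Generator) -> np.ndarray:
    labels = rng.integers(0, n_modules, size=n)
    labels[rng.permutation(n)[:n_modules]] = np.arange(n_modules)  # none empty
    return labels
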