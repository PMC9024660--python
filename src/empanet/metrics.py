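"""Nodal topology measures on binary undirected graphs.

Five per-node measures: degree, betweenness centrality (unnormalized
shortest-path fractions), closeness centrality (Wasserman–Faust composite,
well defined on disconnected graphs), participation coefficient, and
within-module degree z-score. The first three are delegated to networkx;
the module-based pair is computed directly from the adjacency and a
partition.

Conventions
-----------
* Betweenness is the raw sum over unordered node pairs of the fraction of
  shortest paths through the node (no normalization); a ``normalized`` flag
  rescales by 2 / ((n-1)(n-2)).
* Closeness for node v is (r_v / (n-1)) * (r_v / sum of distances), with
  r_v the number of nodes reachable from v (excluding v); isolated nodes
  score 0.
* Within-module degree uses the population standard deviation; modules with
  zero spread yield z = 0 for all members.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

__all__ = [
    "degree",
    "betweenness",
    "closeness",
    "participation",
    "within_module_degree",
    "nodal_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "degree",
    "betweenness",
    "closeness",
    "participation",
    "within_module_degree",
)


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("adjacency must be binary")
    return a


def _check_partition(adj: np.ndarray, partition: np.ndarray) -> np.ndarray:
    p = np.asarray(partition)
    if p.shape != (adj.shape[0],):
        raise ValueError(
            f"partition covers {p.size} nodes but graph has {adj.shape[0]}"
        )
    return p


def degree(adj: np.ndarray) -> np.ndarray:
    """Number of links attached to each node (row sums)."""
    return _check_adjacency(adj).sum(axis=1).astype(int)


def betweenness(adj: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Unnormalized betweenness centrality.

    For node v: sum over unordered pairs (s, t), s != t != v, of
    sigma_st(v) / sigma_st with unit edge lengths; unreachable pairs
    contribute zero.
    """
    a = _check_adjacency(adj)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    return np.array([bc[i] for i in range(a.shape[0])])


def closeness(adj: np.ndarray) -> np.ndarray:
    """Wasserman–Faust closeness, deterministic on disconnected graphs."""
    a = _check_adjacency(adj)
    g = nx.from_numpy_array(a)
    cc = nx.closeness_centrality(g, wf_improved=True)
    return np.array([cc[i] for i in range(a.shape[0])])


def participation(adj: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Participation coefficient P_v = 1 - sum_s (k_vs / k_v)^2.

    k_vs counts v's edges into module s. Nodes with no edges are assigned
    P = 0 (provincial by convention).
    """
    a = _check_adjacency(adj)
    p = _check_partition(a, partition)
    modules = np.unique(p)
    onehot = (p[None, :] == modules[:, None]).astype(float)  # modules x nodes
    k_vs = onehot @ a  # modules x nodes: edges from each node into each module
    k = a.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k > 0, k_vs / k, 0.0)
    out = 1.0 - (frac**2).sum(axis=0)
    out[k == 0] = 0.0
    return out


def within_module_degree(
    adj: np.ndarray, partition: np.ndarray, zscore: bool = True
) -> np.ndarray:
    """Within-module degree, z-scored within each module by default.

    z_v = (kappa_v - mean kappa over v's module) / population SD; modules
    with zero spread (e.g. cliques) give z = 0 for every member. With
    ``zscore=False`` the raw within-module link counts are returned.
    """
    a = _check_adjacency(adj)
    p = _check_partition(a, partition)
    same = p[None, :] == p[:, None]
    kappa = (a * same).sum(axis=1)
    if not zscore:
        return kappa
    z = np.zeros_like(kappa, dtype=float)
    for m in np.unique(p):
        members = p == m
        mu = kappa[members].mean()
        sd = kappa[members].std()  # population SD
        if sd > 0:
            z[members] = (kappa[members] - mu) / sd
    return z


def nodal_metrics(adj: np.ndarray, partition: np.ndarray) -> pd.DataFrame:
    """All five nodal measures for one graph and one partition.

    Returns a frame with one row per node and columns ``node_id`` plus the
    five entries of :data:`METRIC_NAMES`.
    """
    a = _check_adjacency(adj)
    return pd.DataFrame(
        {
            "node_id": np.arange(a.shape[0]),
            "degree": degree(a),
            "betweenness": betweenness(a),
            "closeness": closeness(a),
            "participation": participation(a, partition),
            "within_module_degree": within_module_degree(a, partition),
        }
    )
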