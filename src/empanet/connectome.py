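"""Functional connectome construction.

Node time series are turned into weighted connectomes by Fisher
z-transforming the Pearson correlation between every pair of nodal time
series, then binarized by proportional thresholding: the strongest fraction
of connections (default 10%) is kept, so that every subject's graph has
exactly the same number of edges and density differences cannot drive
between-subject differences in graph metrics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: cap applied to |r| before atanh so perfectly correlated series stay finite
R_CAP = 1.0 - 1e-7

# node counts of the three parcellation components assembled in the registry
N_CORTICAL = 346
N_SUBCORTICAL = 40
N_CEREBELLAR = 32


@dataclass
class Connectome:
    """Square symmetric node-by-node association structure.

    ``kind`` is ``"weighted_z"`` (Fisher-z correlations) or ``"binary"``
    (thresholded adjacency). The diagonal is always exactly zero.
    """

    values: np.ndarray
    kind: str = "weighted_z"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if not np.allclose(v, v.T, equal_nan=False):
            raise ValueError("connectome must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("connectome diagonal must be exactly zero")
        if self.kind == "binary" and not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("binary connectome may contain only {0, 1}")
        if self.kind not in ("weighted_z", "binary"):
            raise ValueError(f"unknown connectome kind {self.kind!r}")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.values != 0, k=1).sum())


def fisher_z_connectome(timeseries: np.ndarray | pd.DataFrame) -> Connectome:
    """Fisher-z correlation connectome from a node-by-time table.

    Entry (i, j) is atanh(r_ij) with r the Pearson correlation between the
    time series of nodes i and j. Correlations with |r| >= 1 - 1e-7 (e.g.
    duplicated series) are capped at that value before the transform, so
    the result is always finite; a warning is logged when capping occurs.

    Parameters
    ----------
    timeseries
        Array or frame of shape (n_nodes, n_timepoints), one row per node.

    Raises
    ------
    ValueError
        If fewer than 3 time points are supplied or any node's series is
        constant (correlation undefined).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (nodes x time)")
    n_nodes, n_time = ts.shape
    if n_time < 3:
        raise ValueError(f"need at least 3 time points, got {n_time}")
    sd = ts.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant time series at node(s) {constant.tolist()}; "
            "correlation is undefined"
        )
    r = np.corrcoef(ts)
    np.fill_diagonal(r, 0.0)
    over = np.abs(r) > R_CAP
    if over.any():
        n_capped = int(np.triu(over, k=1).sum())
        msg = f"capped {n_capped} near-perfect correlation(s) at |r| = 1 - 1e-7"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        r = np.clip(r, -R_CAP, R_CAP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float round-off
    np.fill_diagonal(z, 0.0)
    return Connectome(z, kind="weighted_z")


def proportional_threshold(
    conn: Connectome, density: float = 0.10, absolute: bool = False
) -> Connectome:
    """Binarize a weighted connectome keeping the strongest connections.

    Exactly ``floor(density * n * (n - 1) / 2)`` upper-triangle entries are
    set to one — the largest by signed z value (or |z| when ``absolute``) —
    and mirrored to symmetry. Ties at the cutoff are broken by lexicographic
    (i, j) order so the retained set is deterministic and the edge count is
    identical for every subject at a given density.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    if conn.kind != "weighted_z":
        raise ValueError("proportional_threshold expects a weighted_z connectome")
    n = conn.n_nodes
    n_possible = n * (n - 1) // 2
    n_keep = math.floor(density * n_possible)
    if n_keep == 0:
        raise ValueError(
            f"density {density} retains 0 of {n_possible} edges; increase density"
        )
    iu, ju = np.triu_indices(n, k=1)
    w = conn.values[iu, ju]
    if absolute:
        w = np.abs(w)
    # sort by descending weight, then ascending (i, j); lexsort: last key primary
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_keep]
    adj = np.zeros((n, n))
    adj[iu[keep], ju[keep]] = 1.0
    adj = adj + adj.T
    return Connectome(adj, kind="binary")


# ---------------------------------------------------------------------------
# node registry


@dataclass
class NodeRegistry:
    """Table of nodes: id, label, atlas component, MNI coordinates (mm)."""

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("node_id", "label", "component", "x", "y", "z")
    COMPONENTS = ("cortical", "subcortical", "cerebellar")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"node registry missing columns {sorted(missing)}")
        ids = self.table["node_id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise ValueError("node ids must be unique")
        if not np.array_equal(np.sort(ids), np.arange(len(ids))):
            raise ValueError("node ids must be contiguous from 0")
        bad = set(self.table["component"]) - set(self.COMPONENTS)
        if bad:
            raise ValueError(f"unknown atlas component(s) {sorted(bad)}")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    def component_counts(self) -> dict[str, int]:
        return self.table["component"].value_counts().to_dict()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NodeRegistry":
        return cls(pd.read_csv(path))


def make_node_registry(
    n_cortical: int = N_CORTICAL,
    n_subcortical: int = N_SUBCORTICAL,
    n_cerebellar: int = N_CEREBELLAR,
    seed: int = 0,
) -> NodeRegistry:
    """Assemble a synthetic node registry from the three atlas components.

    The default counts (346 cortical + 40 subcortical + 32 cerebellar = 418
    parcels) mirror a standard whole-brain parcellation combining cortical,
    subcortical and cerebellar atlases. Labels and MNI coordinates are
    synthetic placeholders (coordinates drawn uniformly within plausible
    component bounding boxes), sufficient for bookkeeping and reporting; they
    carry no anatomical claim.
    """
    rng = np.random.default_rng(seed)
    specs = [
        ("cortical", n_cortical, (-70, 70), (-105, 70), (-45, 75)),
        ("subcortical", n_subcortical, (-35, 35), (-40, 25), (-25, 25)),
        ("cerebellar", n_cerebellar, (-50, 50), (-90, -40), (-60, -10)),
    ]
    rows = []
    node_id = 0
    for comp, count, xb, yb, zb in specs:
        for k in range(count):
            rows.append(
                {
                    "node_id": node_id,
                    "label": f"{comp[:4]}_{k:03d}",
                    "component": comp,
                    "x": round(float(rng.uniform(*xb)), 1),
                    "y": round(float(rng.uniform(*yb)), 1),
                    "z": round(float(rng.uniform(*zb)), 1),
                }
            )
            node_id += 1
    return NodeRegistry(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# delimited-text I/O


def load_timeseries(path: str | Path, delimiter: str = ",") -> np.ndarray:
    """Read a node-by-time matrix from delimited text."""
    return np.loadtxt(path, delimiter=delimiter, ndmin=2)


def load_connectome(
    path: str | Path, kind: str = "weighted_z", delimiter: str = ","
) -> Connectome:
    """Read a square connectivity matrix from delimited text."""
    values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return Connectome(values, kind=kind)


def save_connectome(conn: Connectome, path: str | Path, delimiter: str = ",") -> None:
    fmt = "%d" if conn.kind == "binary" else "%.8g"
    np.savetxt(path, conn.values, delimiter=delimiter, fmt=fmt)
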