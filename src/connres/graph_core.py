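"""Thresholding, binarization, graph metrics and the density/AUC machinery.

A weighted connectome is first cleaned with an absolute threshold (w > 0,
negative correlations discarded), then represented as a stack of binary
graphs obtained by proportional thresholding at densities
delta in {0.1, ..., 1.0}: at density delta the round(delta * P) strongest of
the P positive edges are kept. Each metric M is evaluated on every graph of
the stack and summarized by the area under the M(delta) curve over
delta in [0, 1] (trapezoid, with the analytic delta = 0 endpoint where every
metric of the edgeless graph is 0). The AUC is the threshold-free proxy used
by all downstream analyses.

Metrics (binary, undirected, Rubinov-Sporns conventions):

- global efficiency  E_glob = mean over ordered pairs of 1/d(i, j), 1/inf = 0
- fixed-partition modularity  Q = sum_s [e_s/m - (d_s/2m)^2]
- mean clustering coefficient  CC = mean_i 2 t_i / (k_i (k_i - 1))
- participation coefficient  PC_i = 1 - sum_s (k_is / k_i)^2
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import ModulePartition, WeightedConnectome

__all__ = [
    "DEFAULT_GRID",
    "METRICS",
    "BinaryGraph",
    "DensityMetricCurve",
    "positive_threshold",
    "proportional_binarize",
    "density_stack",
    "global_efficiency",
    "modularity_fixed",
    "clustering_mean",
    "participation",
    "metric_curve",
    "auc_of_curve",
    "connectome_metric_profile",
    "nodal_pc_auc",
]

#: the ten densities of the proportional-threshold sweep
DEFAULT_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 11))

#: whole-brain metrics understood by :func:`metric_curve`
METRICS = ("global_efficiency", "modularity", "clustering", "participation_mean")


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected binary graph: symmetric hollow 0/1 adjacency matrix."""

    node_ids: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        a = np.asarray(self.adjacency, dtype=bool)
        n = len(self.node_ids)
        if a.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(a, a.T) or a.diagonal().any():
            raise ValueError("adjacency must be symmetric and hollow")
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return 0.0 if n < 2 else 2.0 * self.n_edges / (n * (n - 1))


@dataclass(frozen=True)
class DensityMetricCurve:
    """Metric values along the density grid plus the AUC scalar."""

    metric_name: str
    grid: tuple[float, ...]
    values: tuple[float, ...]
    auc: float


# ---------------------------------------------------------------------------
# thresholding

def positive_threshold(conn: WeightedConnectome) -> WeightedConnectome:
    """Zero every non-positive off-diagonal weight (absolute threshold w > 0)."""
    w = conn.weights.copy()
    off = ~np.eye(conn.n_nodes, dtype=bool)
    w[off & (w <= 0.0)] = 0.0
    return WeightedConnectome(conn.node_ids, w, conn.removed_nodes)


def _edge_order(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positive upper-triangle edges sorted by weight desc, (i, j) lexicographic.

    The lexicographic tie-break makes proportional thresholding reproducible
    when weights tie.
    """
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    pos = w > 0.0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def _edge_count(delta: float, n_positive: int) -> int:
    """round-half-away-from-zero(delta * P), clipped to [0, P]."""
    k = math.floor(delta * n_positive + 0.5)
    return min(max(k, 0), n_positive)


def proportional_binarize(conn: WeightedConnectome, delta: float) -> BinaryGraph:
    """Keep the ``round(delta * P)`` strongest positive edges, binarized.

    ``delta = 0`` gives the edgeless graph, ``delta = 1`` keeps every
    positive edge.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"density delta must lie in [0, 1], got {delta}")
    iu, ju, _ = _edge_order(conn.weights)
    k = _edge_count(delta, len(iu))
    n = conn.n_nodes
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[:k], ju[:k]] = True
    return BinaryGraph(conn.node_ids, adj | adj.T)


def density_stack(
    conn: WeightedConnectome, grid: Sequence[float] = DEFAULT_GRID
) -> list[BinaryGraph]:
    """One binary graph per grid density; edge sets are nested along the grid."""
    iu, ju, _ = _edge_order(conn.weights)
    n = conn.n_nodes
    out = []
    for delta in grid:
        if not 0.0 <= delta <= 1.0:
            raise ValueError(f"density delta must lie in [0, 1], got {delta}")
        k = _edge_count(delta, len(iu))
        adj = np.zeros((n, n), dtype=bool)
        adj[iu[:k], ju[:k]] = True
        out.append(BinaryGraph(conn.node_ids, adj | adj.T))
    return out


# ---------------------------------------------------------------------------
# metric kernels on raw adjacency arrays (shared by the public wrappers and
# the batched profile used in attack batteries)

def _eglob_adj(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    a = adj.astype(np.float64)
    reached = adj.copy()
    np.fill_diagonal(reached, True)
    inv_sum = float(adj.sum())  # distance-1 pairs (ordered)
    dist = 1
    frontier = reached
    while True:
        dist += 1
        nxt = (frontier.astype(np.float64) @ a) > 0.5
        new = nxt & ~reached
        if not new.any():
            break
        inv_sum += float(new.sum()) / dist
        reached |= new
        frontier = reached
    return inv_sum / (n * (n - 1))


def _modularity_adj(adj: np.ndarray, onehot: np.ndarray) -> float:
    deg = adj.sum(axis=1).astype(np.float64)
    two_m = float(deg.sum())
    if two_m == 0.0:
        return 0.0  # edgeless graph: Q = 0 by convention
    a = adj.astype(np.float64)
    e_s = np.einsum("is,ij,js->s", onehot, a, onehot) / 2.0  # intra-module edges
    d_s = deg @ onehot
    return float(np.sum(e_s / (two_m / 2.0) - (d_s / two_m) ** 2))


def _clustering_adj(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 3:
        raise ValueError("clustering needs at least 3 nodes")
    a = adj.astype(np.float64)
    deg = a.sum(axis=1)
    tri2 = (a * (a @ a)).sum(axis=1)  # = 2 * triangles through each node
    denom = deg * (deg - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0.0, tri2 / denom, 0.0)
    return float(c.mean())


def _participation_adj(adj: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    a = adj.astype(np.float64)
    k_is = a @ onehot
    k = a.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(k[:, None] > 0.0, k_is / k[:, None], 0.0)
    pc = 1.0 - (frac**2).sum(axis=1)
    return np.where(k > 0.0, pc, 0.0)  # isolated nodes: PC = 0 by convention


def _onehot(modules: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(modules, return_inverse=True)
    out = np.zeros((len(modules), len(uniq)), dtype=np.float64)
    out[np.arange(len(modules)), inv] = 1.0
    return out


# ---------------------------------------------------------------------------
# public per-graph metrics

def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    return _eglob_adj(g.adjacency)


def modularity_fixed(g: BinaryGraph, partition: ModulePartition) -> float:
    """Newman modularity evaluated at the fixed a-priori partition."""
    modules = partition.align(g.node_ids)
    return _modularity_adj(g.adjacency, _onehot(modules))


def clustering_mean(g: BinaryGraph) -> float:
    """Network-average clustering coefficient (degree < 2 nodes contribute 0)."""
    return _clustering_adj(g.adjacency)


def participation(g: BinaryGraph, partition: ModulePartition) -> dict[str, float]:
    """Participation coefficient per node; isolated nodes get 0."""
    modules = partition.align(g.node_ids)
    pc = _participation_adj(g.adjacency, _onehot(modules))
    return dict(zip(g.node_ids, pc.tolist()))


# ---------------------------------------------------------------------------
# curves and AUC

def auc_of_curve(
    grid: Sequence[float],
    values: Sequence[float],
    value_at_zero: float = 0.0,
) -> float:
    """Trapezoidal integral of M(delta) over [0, 1].

    The grid starts at delta = 0.1; the delta = 0 endpoint is supplied
    analytically (``value_at_zero``, 0 for every metric since the edgeless
    graph scores 0 on all of them).
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.shape != values.shape or grid.ndim != 1:
        raise ValueError("grid and values must be 1-D and aligned")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted strictly ascending")
    x = np.concatenate([[0.0], grid])
    y = np.concatenate([[value_at_zero], values])
    return float(np.trapezoid(y, x))


def connectome_metric_profile(
    conn: WeightedConnectome,
    partition: ModulePartition | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    metrics: Sequence[str] = ("global_efficiency", "modularity", "clustering"),
    nodal_pc: bool = False,
) -> dict:
    """Evaluate several metrics on one shared density stack.

    Returns ``{"grid": ..., "curves": {metric: values}, "auc": {metric: scalar},
    "nodal_pc_auc": {node: scalar} (optional)}``. This is the batched engine
    behind :func:`metric_curve`; attack batteries call it directly so the
    stack is built once per matrix.
    """
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    need_partition = nodal_pc or any(
        m in ("modularity", "participation_mean") for m in metrics
    )
    onehot = None
    if need_partition:
        if partition is None:
            raise ValueError("partition required for modularity/participation")
        onehot = _onehot(partition.align(conn.node_ids))

    iu, ju, _ = _edge_order(conn.weights)
    n = conn.n_nodes
    curves: dict[str, list[float]] = {m: [] for m in metrics}
    pc_rows: list[np.ndarray] = []
    adj = np.zeros((n, n), dtype=bool)
    prev_k = 0
    for delta in grid:
        k = _edge_count(delta, len(iu))
        if k > prev_k:  # nested stack: add the newly admitted edges
            adj[iu[prev_k:k], ju[prev_k:k]] = True
            adj[ju[prev_k:k], iu[prev_k:k]] = True
            prev_k = k
        for m in metrics:
            if m == "global_efficiency":
                curves[m].append(_eglob_adj(adj))
            elif m == "modularity":
                curves[m].append(_modularity_adj(adj, onehot))
            elif m == "clustering":
                curves[m].append(_clustering_adj(adj))
            elif m == "participation_mean":
                curves[m].append(float(_participation_adj(adj, onehot).mean()))
        if nodal_pc:
            pc_rows.append(_participation_adj(adj, onehot))

    out = {
        "grid": tuple(float(d) for d in grid),
        "curves": {m: tuple(v) for m, v in curves.items()},
        "auc": {m: auc_of_curve(grid, v) for m, v in curves.items()},
    }
    if nodal_pc:
        pc_mat = np.stack(pc_rows, axis=1)  # node x density
        aucs = [auc_of_curve(grid, row) for row in pc_mat]
        out["nodal_pc_auc"] = dict(zip(conn.node_ids, aucs))
        out["nodal_pc_curves"] = pc_mat
    return out


def metric_curve(
    conn: WeightedConnectome,
    metric_name: str,
    partition: ModulePartition | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
) -> DensityMetricCurve:
    """M(delta) on the density stack plus its AUC, for one whole-brain metric."""
    prof = connectome_metric_profile(conn, partition, grid, metrics=(metric_name,))
    return DensityMetricCurve(
        metric_name=metric_name,
        grid=prof["grid"],
        values=prof["curves"][metric_name],
        auc=prof["auc"][metric_name],
    )


def nodal_pc_auc(
    conn: WeightedConnectome,
    partition: ModulePartition,
    grid: Sequence[float] = DEFAULT_GRID,
) -> Mapping[str, float]:
    """AUC-over-density of the participation coefficient, per node."""
    prof = connectome_metric_profile(
        conn, partition, grid, metrics=(), nodal_pc=True
    )
    return prof["nodal_pc_auc"]
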