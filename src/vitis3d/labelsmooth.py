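"""Spatial label smoothing by exact binary graph-cut energy minimization.

Points are nodes of a radius-neighborhood graph; the energy of a labeling L
is

    E(L) = sum_i (1 - P_i(L_i)) + penalty * sum_{(i,j) in edges} 1[L_i != L_j]

with P the class posteriors from the classifier and a uniform Potts penalty
for diverging neighbor labels. For two labels the Potts energy is
submodular, so a single s-t max-flow / min-cut yields the exact global
minimizer. Capacities are scaled to integers adaptively so the total
capacity stays below 2^31 (scipy's max-flow works on integer capacities);
the reported energy is recomputed in float64 from the returned labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from scipy.spatial import cKDTree

from .pointcloud import PointCloud


@dataclass
class NeighborGraph:
    """Undirected edges (i, j) with i < j, no self-loops or duplicates."""

    edges: np.ndarray            # (E, 2) int64
    radius: float
    n_nodes: int

    def __post_init__(self) -> None:
        self.edges = np.ascontiguousarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if len(self.edges):
            if (self.edges[:, 0] >= self.edges[:, 1]).any():
                raise ValueError("edges must satisfy i < j")
            uniq = np.unique(self.edges, axis=0)
            if uniq.shape[0] != self.edges.shape[0]:
                raise ValueError("duplicate edges")


def build_neighbor_graph(cloud_or_coords, radius: float) -> NeighborGraph:
    """Edge (i, j) iff ||p_i - p_j|| <= radius, i != j."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = getattr(cloud_or_coords, "coords", cloud_or_coords)
    coords = np.asarray(coords, dtype=np.float64)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0])) if len(pairs) else slice(None)
    return NeighborGraph(edges=pairs[order], radius=radius, n_nodes=coords.shape[0])


def label_energy(labels: np.ndarray, posteriors: np.ndarray,
                 graph: NeighborGraph, penalty: float) -> float:
    """E(L) = sum_i (1 - P_i(L_i)) + penalty * #{edges with differing labels}."""
    labels = np.asarray(labels, dtype=np.int64)
    unary = 1.0 - posteriors[np.arange(len(labels)), labels]
    if len(graph.edges):
        cut = (labels[graph.edges[:, 0]] != labels[graph.edges[:, 1]]).sum()
    else:
        cut = 0
    return float(unary.sum() + penalty * cut)


def smooth_labels(posteriors: np.ndarray, graph: NeighborGraph, penalty: float):
    """Exact global minimizer of the binary Potts energy.

    Returns ``(labels, energy)``. With ``penalty = 0`` the result is the
    per-point argmax (ties to class 0).
    """
    post = np.asarray(posteriors, dtype=np.float64)
    if post.ndim != 2 or post.shape[1] != 2:
        raise ValueError("posteriors must be (N, 2)")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    n = post.shape[0]
    if graph.n_nodes != n:
        raise ValueError("graph size does not match posteriors")
    unary = 1.0 - post  # unary[i, l] = cost of assigning label l

    if penalty == 0.0 or len(graph.edges) == 0:
        labels = (post[:, 1] > post[:, 0]).astype(np.int64)
        return labels, label_energy(labels, post, graph, penalty)

    edges = graph.edges
    n_edges = edges.shape[0]
    # adaptive integer scaling: total capacity must stay below int32 range
    total_units = float(unary.sum() + 2.0 * penalty * n_edges) + 1.0
    scale = min(1e8, (2**31 - 64) / total_units)
    source, sink = n, n + 1

    cap_s = np.rint(unary[:, 1] * scale).astype(np.int32)   # cut when label 1
    cap_t = np.rint(unary[:, 0] * scale).astype(np.int32)   # cut when label 0
    w = np.int32(round(penalty * scale))

    rows = np.concatenate([
        np.full(n, source), np.arange(n),
        edges[:, 0], edges[:, 1],
    ])
    cols = np.concatenate([
        np.arange(n), np.full(n, sink),
        edges[:, 1], edges[:, 0],
    ])
    caps = np.concatenate([
        cap_s, cap_t,
        np.full(n_edges, w, dtype=np.int32), np.full(n_edges, w, dtype=np.int32),
    ])
    keep = caps > 0
    cap = csr_matrix((caps[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2),
                     dtype=np.int32)
    result = maximum_flow(cap, source, sink)
    residual = cap - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, source, directed=True,
                                    return_predecessors=False)
    labels = np.ones(n, dtype=np.int64)
    reachable = reachable[reachable < n]
    labels[reachable] = 0
    return labels, label_energy(labels, post, graph, penalty)
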