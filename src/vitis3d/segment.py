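"""Bunch candidate segmentation: two-stage connected components with size
filtering.

Grape-bunch-labeled points are partitioned into components: maximal sets of
points linked by hops no longer than a distance threshold (about 5 mm for
the first pass). Components smaller than a minimum point count are deleted
(misclassification residue); components larger than a maximum count —
usually several bunches fused together — are re-partitioned at a tighter
threshold (about 1 mm), and the split fragments are re-filtered with the
minimum size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree


@dataclass
class Component:
    """A set of point indices (into the classified cloud) with a stage tag."""

    indices: np.ndarray
    stage: str = "first-pass"   # or "split"

    def __post_init__(self) -> None:
        self.indices = np.ascontiguousarray(np.sort(self.indices), dtype=np.int64)

    def __len__(self) -> int:
        return self.indices.shape[0]


@dataclass
class SegmentParams:
    cc_dist_1: float = 0.005
    cc_dist_2: float = 0.001
    min_points: int = 400       # VSP default; 300 for the denser SMPH canopy
    max_points: int = 5000      # VSP default; 3000 for SMPH

    def __post_init__(self) -> None:
        if not (0 < self.cc_dist_2 < self.cc_dist_1):
            raise ValueError("need 0 < cc_dist_2 < cc_dist_1")
        if not (1 <= self.min_points < self.max_points):
            raise ValueError("need 1 <= min_points < max_points")


def connected_components(indices: np.ndarray, coords: np.ndarray, dist: float,
                         stage: str = "first-pass") -> List[Component]:
    """Partition ``indices`` into components at hop distance ``dist``.

    Two points share a component iff they are linked by a chain of hops each
    no longer than ``dist``. Components are returned sorted by their
    smallest member index (deterministic).
    """
    if dist <= 0:
        raise ValueError("dist must be positive")
    indices = np.ascontiguousarray(indices, dtype=np.int64)
    if indices.size == 0:
        return []
    pts = coords[indices]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(dist, output_type="ndarray")
    n = indices.size
    if len(pairs):
        adj = csr_matrix((np.ones(len(pairs), dtype=np.int8),
                          (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = csr_matrix((n, n), dtype=np.int8)
    n_comp, labels = _cc(adj, directed=False)
    comps = [Component(indices=indices[labels == c], stage=stage)
             for c in range(n_comp)]
    comps.sort(key=lambda c: int(c.indices[0]))
    return comps


def filter_small(components: List[Component], min_points: int):
    """Keep components with at least ``min_points`` points.

    Returns ``(kept, deleted)``.
    """
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    kept = [c for c in components if len(c) >= min_points]
    deleted = [c for c in components if len(c) < min_points]
    return kept, deleted


def split_large(components: List[Component], coords: np.ndarray,
                max_points: int, cc_dist_2: float,
                min_points: int = 1) -> List[Component]:
    """Re-partition oversized components at the tighter distance.

    Components with more than ``max_points`` points (usually several fused
    bunches) are replaced by their connected components at ``cc_dist_2``;
    split fragments smaller than ``min_points`` are dropped.
    """
    out: List[Component] = []
    for comp in components:
        if len(comp) <= max_points:
            out.append(comp)
            continue
        fragments = connected_components(comp.indices, coords, cc_dist_2, stage="split")
        fragments, _ = filter_small(fragments, min_points)
        out.extend(fragments)
    return out


def segment_bunches(bunch_indices: np.ndarray, coords: np.ndarray,
                    params: SegmentParams | None = None) -> List[Component]:
    """Full two-stage segmentation of bunch-labeled points."""
    params = params or SegmentParams()
    comps = connected_components(bunch_indices, coords, params.cc_dist_1)
    comps, _ = filter_small(comps, params.min_points)
    comps = split_large(comps, coords, params.max_points, params.cc_dist_2,
                        params.min_points)
    return comps


def component_labels(components: List[Component], n_points: int) -> np.ndarray:
    """Per-point component id (-1 for points in no surviving component)."""
    labels = np.full(n_points, -1, dtype=np.int64)
    for cid, comp in enumerate(components):
        labels[comp.indices] = cid
    return labels
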