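"""In-memory containers: colored point cloud and camera track.

Coordinates are always meters. Colors are RGB in [0, 1] regardless of the
bit depth of the source file (8-bit channels are divided by 255 on load).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class PointCloud:
    """N colored 3D points with optional normals, labels and class posteriors.

    Attributes
    ----------
    coords : (N, 3) float64
        Point positions in meters.
    colors : (N, 3) float64 or None
        RGB in [0, 1].
    normals : (N, 3) float64 or None
        Unit normals; rows may be NaN where undefined.
    labels : (N,) int or None
        Class labels (0 = canopy, 1 = grape bunch) or any integer labeling.
    posteriors : (N, n_classes) float64 or None
        Per-point class membership probabilities, rows summing to 1.
    """

    coords: np.ndarray
    colors: Optional[np.ndarray] = None
    normals: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    posteriors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")
        if self.colors is not None:
            self.colors = np.ascontiguousarray(self.colors, dtype=np.float64)
            if self.colors.shape != self.coords.shape:
                raise ValueError("colors must match coords shape")
            if self.colors.min(initial=0.0) < -1e-9 or self.colors.max(initial=0.0) > 1 + 1e-9:
                raise ValueError("colors must lie in [0, 1]")
            np.clip(self.colors, 0.0, 1.0, out=self.colors)
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.coords.shape:
                raise ValueError("normals must match coords shape")
            norms = np.linalg.norm(self.normals, axis=1)
            ok = np.isnan(norms) | (np.abs(norms - 1.0) <= 1e-9)
            if not ok.all():
                raise ValueError("normals must be unit vectors (or NaN where undefined)")
        if self.labels is not None:
            self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self),):
                raise ValueError("labels must be (N,)")
        if self.posteriors is not None:
            self.posteriors = np.ascontiguousarray(self.posteriors, dtype=np.float64)
            if self.posteriors.ndim != 2 or self.posteriors.shape[0] != len(self):
                raise ValueError("posteriors must be (N, n_classes)")
            if self.posteriors.min(initial=0.0) < -1e-9 or self.posteriors.max(initial=0.0) > 1 + 1e-9:
                raise ValueError("posteriors must lie in [0, 1]")
            if not np.allclose(self.posteriors.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("posterior rows must sum to 1")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def select(self, index) -> "PointCloud":
        """Return a new cloud restricted to ``index`` (mask or integer index)."""
        return PointCloud(
            coords=self.coords[index],
            colors=None if self.colors is None else self.colors[index],
            normals=None if self.normals is None else self.normals[index],
            labels=None if self.labels is None else self.labels[index],
            posteriors=None if self.posteriors is None else self.posteriors[index],
        )

    def copy(self) -> "PointCloud":
        return self.select(slice(None))


@dataclass
class CameraTrack:
    """Ordered 3D camera positions (meters) in the same frame as the cloud."""

    positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (M, 3)")
        if self.positions.shape[0] < 1:
            raise ValueError("camera track must contain at least one position")
        if not np.isfinite(self.positions).all():
            raise ValueError("camera positions must be finite")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def nearest(self, point: np.ndarray) -> np.ndarray:
        """Camera position with minimum Euclidean distance to ``point``."""
        d2 = ((self.positions - np.asarray(point)) ** 2).sum(axis=1)
        return self.positions[int(np.argmin(d2))]
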