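"""Pipeline configuration: every tunable of the downstream stages.

All lengths are meters internally; the millimeter values familiar from the
field protocol (1 mm subsampling, 3 mm normal radius, 9 mm histogram radius,
5 mm / 1 mm component distances, 4-10 mm berry radii) are converted here at
the configuration boundary, once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    # -- preprocess ---------------------------------------------------------
    v_threshold: float = 0.10        # HSV brightness cutoff for background
    sor_k: int = 6                   # neighbors for statistical outlier removal
    sor_sigma_mult: float = 1.0
    mls_radius: float = 0.004        # m
    mls_order: int = 2
    subsample_min_dist: float = 0.001  # m; 1 mm point-to-point spacing

    # -- features -----------------------------------------------------------
    r_N: float = 0.003               # m; normal estimation radius
    r_H: float = 0.009               # m; histogram radius (~1.5 berries)

    # -- classifier ---------------------------------------------------------
    ivm_gamma: Optional[float] = None  # None -> median heuristic
    ivm_lambda: float = 1e-3
    ivm_max_import: int = 200
    ivm_tol: float = 1e-4

    # -- label smoothing ----------------------------------------------------
    smooth_radius: float = 0.003     # m
    smooth_penalty: float = 0.5      # Potts weight

    # -- segmentation -------------------------------------------------------
    cc_dist_1: float = 0.005         # m; first connected-components pass
    cc_dist_2: float = 0.001         # m; second pass for fused components
    min_points: int = 400            # VSP default (SMPH: 300)
    max_points: int = 5000           # VSP default (SMPH: 3000)

    # -- findBerries --------------------------------------------------------
    r_min: float = 0.004             # m; valid berry radius range
    r_max: float = 0.010             # m
    fit_radius: Optional[float] = None  # None -> 1.2 * r_max
    inlier_tol: float = 0.10         # fraction of sphere radius
    min_support_ratio: float = 0.5
    min_fit_points: int = 10
    line_tol: float = 0.0015         # m; valley-test line tolerance
    min_line_points: int = 3         # see BerryParams: density-consistent at 1 mm
    overlap_ratio: float = 0.25

    # -- yield --------------------------------------------------------------
    min_berries: int = 3             # components with fewer berries rejected

    # -- reproducibility ----------------------------------------------------
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "mls_radius", "subsample_min_dist", "r_N", "r_H",
            "smooth_radius", "cc_dist_1", "cc_dist_2", "r_min", "r_max",
            "inlier_tol", "line_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 <= self.v_threshold <= 1.0):
            raise ValueError("v_threshold must lie in [0, 1]")
        if self.sor_k < 3:
            raise ValueError("sor_k must be >= 3")
        if self.sor_sigma_mult <= 0:
            raise ValueError("sor_sigma_mult must be > 0")
        if self.mls_order not in (1, 2, 3):
            raise ValueError("mls_order must be 1, 2 or 3")
        if self.r_H <= self.r_N:
            raise ValueError("r_H must exceed r_N")
        if self.r_min >= self.r_max:
            raise ValueError("berry radius range must satisfy r_min < r_max")
        if self.cc_dist_2 >= self.cc_dist_1:
            raise ValueError("cc_dist_2 must be smaller than cc_dist_1")
        if self.min_points >= self.max_points:
            raise ValueError("min_points must be smaller than max_points")
        for name in ("min_support_ratio", "overlap_ratio", "inlier_tol"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.smooth_penalty < 0:
            raise ValueError("smooth_penalty must be >= 0")

    @property
    def effective_fit_radius(self) -> float:
        return self.fit_radius if self.fit_radius is not None else 1.2 * self.r_max

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a stable per-stage RNG seed (< 2^31) from the pipeline seed.

    Uses a fixed FNV-1a hash of the stage name so stages are independently
    reproducible regardless of execution order.
    """
    h = 2166136261
    for byte in stage.encode():
        h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return (int(base_seed) * 1000003 + h) % (2**31 - 1)
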