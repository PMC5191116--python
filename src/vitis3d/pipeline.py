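"""End-to-end orchestration: preprocess -> features -> classify -> smooth ->
segment -> findBerries -> yield report.

Each stage's output can be persisted and reloaded, so a run can resume from
any stage. One pipeline seed fans out into stable per-stage seeds.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from . import io as vio
from .classifier import IvmModel, TrainingSet, assign_labels, predict_proba, train_ivm
from .config import PipelineConfig, stage_seed
from .features import SfhParams, extract_features
from .findberries import Berry, BerryParams, find_berries
from .labelsmooth import build_neighbor_graph, label_energy, smooth_labels
from .pointcloud import CameraTrack, PointCloud
from .preprocess import preprocess
from .segment import SegmentParams, component_labels, segment_bunches
from .yieldreport import YieldReport, finalize_yield


@dataclass
class RunManifest:
    config: dict
    seed: int
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config, "seed": self.seed, "counts": self.counts,
            "timings": self.timings, "outputs": self.outputs}, indent=2))


def berry_params_from_config(config: PipelineConfig) -> BerryParams:
    return BerryParams(
        r_min=config.r_min, r_max=config.r_max, fit_radius=config.fit_radius,
        inlier_tol=config.inlier_tol, min_support_ratio=config.min_support_ratio,
        min_fit_points=config.min_fit_points, line_tol=config.line_tol,
        min_line_points=config.min_line_points, overlap_ratio=config.overlap_ratio,
        seed=stage_seed(config.seed, "findberries"))


def train_from_labeled_cloud(cloud: PointCloud, cameras: CameraTrack,
                             config: PipelineConfig,
                             points_per_class: int = 600) -> IvmModel:
    """Train the IVM from a labeled cloud, sampling a balanced training set.

    About 600 points per class (canopy / grape bunch) are drawn at random
    from the labeled points; features are computed on the full cloud so the
    training neighborhoods match deployment conditions.
    """
    if cloud.labels is None:
        raise ValueError("training requires per-point labels")
    feats = extract_features(cloud, cameras, SfhParams(r_N=config.r_N, r_H=config.r_H))
    rng = np.random.default_rng(stage_seed(config.seed, "train-sample"))
    rows = []
    for cls in (0, 1):
        idx = np.flatnonzero((cloud.labels == cls) & feats.valid)
        if idx.size < 10:
            raise ValueError(f"not enough labeled points for class {cls}")
        take = min(points_per_class, idx.size)
        rows.append(rng.choice(idx, size=take, replace=False))
    rows = np.concatenate(rows)
    train = TrainingSet(features=feats.values[rows], labels=cloud.labels[rows])
    return train_ivm(train, gamma=config.ivm_gamma, lam=config.ivm_lambda,
                     max_import=config.ivm_max_import, tol=config.ivm_tol,
                     seed=stage_seed(config.seed, "train-ivm"))


@dataclass
class PipelineResult:
    cloud: PointCloud               # preprocessed cloud
    posteriors: np.ndarray
    labels_initial: np.ndarray
    labels_smoothed: np.ndarray
    components: list
    berries_per_component: List[List[Berry]]
    report: YieldReport
    manifest: RunManifest


def run_pipeline(cloud: PointCloud, cameras: CameraTrack, model: IvmModel,
                 config: Optional[PipelineConfig] = None,
                 outdir: Optional[Path] = None) -> PipelineResult:
    """Run all stages on a raw cloud; optionally persist intermediates."""
    config = config or PipelineConfig()
    if cameras is None or len(cameras) == 0:
        raise ValueError("findBerries requires a camera track; none was provided")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    manifest.counts["input_points"] = len(cloud)
    t0 = time.perf_counter()

    clean, counts = preprocess(
        cloud, v_threshold=config.v_threshold, sor_k=config.sor_k,
        sor_sigma_mult=config.sor_sigma_mult, mls_radius=config.mls_radius,
        mls_order=config.mls_order, subsample_min_dist=config.subsample_min_dist)
    manifest.counts.update(counts)
    manifest.timings["preprocess_s"] = round(time.perf_counter() - t0, 3)
    if outdir is not None:
        vio.write_ply(clean, outdir / "preprocessed.ply")
        manifest.outputs["preprocessed"] = str(outdir / "preprocessed.ply")

    t0 = time.perf_counter()
    feats = extract_features(clean, cameras, SfhParams(r_N=config.r_N, r_H=config.r_H))
    manifest.timings["features_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    post, _ = predict_proba(model, feats)
    labels_initial = assign_labels(post)
    manifest.counts["initial_bunch_points"] = int(labels_initial.sum())
    manifest.timings["classify_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    graph = build_neighbor_graph(clean, config.smooth_radius)
    energy_before = label_energy(labels_initial, post, graph, config.smooth_penalty)
    labels_smoothed, energy_after = smooth_labels(post, graph, config.smooth_penalty)
    manifest.counts["smoothed_bunch_points"] = int(labels_smoothed.sum())
    manifest.counts["energy_before"] = round(energy_before, 6)
    manifest.counts["energy_after"] = round(energy_after, 6)
    manifest.timings["smooth_s"] = round(time.perf_counter() - t0, 3)
    if outdir is not None:
        vio.write_posteriors(post, outdir / "posteriors.txt")
        vio.write_labels(labels_smoothed, outdir / "labels.txt")

    t0 = time.perf_counter()
    seg_params = SegmentParams(cc_dist_1=config.cc_dist_1, cc_dist_2=config.cc_dist_2,
                               min_points=config.min_points, max_points=config.max_points)
    components = segment_bunches(np.flatnonzero(labels_smoothed == 1),
                                 clean.coords, seg_params)
    manifest.counts["components"] = len(components)
    manifest.timings["segment_s"] = round(time.perf_counter() - t0, 3)
    if outdir is not None:
        vio.write_labels(component_labels(components, len(clean)),
                         outdir / "components.txt")

    t0 = time.perf_counter()
    bparams = berry_params_from_config(config)
    berries_per_component: List[List[Berry]] = []
    for k, comp in enumerate(components):
        local = find_berries(clean.coords[comp.indices], cameras, bparams,
                             seed=stage_seed(config.seed, f"findberries-{k}"))
        berries_per_component.append(local)
    manifest.timings["findberries_s"] = round(time.perf_counter() - t0, 3)

    report = finalize_yield(components, berries_per_component,
                            min_berries=config.min_berries, coords=clean.coords)
    manifest.counts["bunch_count"] = report.bunch_count
    manifest.counts["berry_count"] = report.berry_count
    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        _write_berry_csv(components, berries_per_component, clean.coords,
                         outdir / "berries.csv")
        manifest.outputs["report"] = str(outdir / "report.json")
        manifest.save(outdir / "manifest.json")

    return PipelineResult(cloud=clean, posteriors=post,
                          labels_initial=labels_initial,
                          labels_smoothed=labels_smoothed,
                          components=components,
                          berries_per_component=berries_per_component,
                          report=report, manifest=manifest)


def _write_berry_csv(components, berries_per_component, coords, path) -> None:
    with open(path, "w") as fh:
        fh.write("component,center_x,center_y,center_z,radius_m,support\n")
        for k, berries in enumerate(berries_per_component):
            for b in berries:
                fh.write(f"{k},{b.center[0]:.6f},{b.center[1]:.6f},{b.center[2]:.6f},"
                         f"{b.radius:.6f},{b.support.size}\n")
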