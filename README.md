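# vitis3d

Yield-parameter estimation for grapevines from colored 3D point clouds.

Vineyard yield is forecast from three parameters — the number of grape
bunches, the number of berries and the berry diameter — that are
traditionally collected by hand. `vitis3d` derives all three automatically
from a multi-view-stereo (MVS) point cloud of a vine row (PLY, meters, RGB)
plus the camera track of the reconstruction:

1. **Preprocess** — HSV brightness thresholding removes the dark night-time
   background, a statistical outlier filter (mean k-NN distance vs.
   μ + ασ) drops isolated points, moving-least-squares projection smooths
   surfaces, and the cloud is subsampled to a 1 mm minimum point spacing.
2. **Features** — every point gets a 128-dim descriptor: a 125-bin surface
   feature histogram (SFH; joint 5×5×5 histogram of the three Darboux-frame
   angles (α, φ, θ) over all point pairs within r_H = 9 mm, normals from
   r_N = 3 mm PCA) plus the HSV color triplet. The SFH is pose-invariant
   and separates the "valley-ridge" geometry of berry clusters from locally
   planar leaves.
3. **Classify** — an import vector machine (sparse greedy kernel logistic
   regression, ~600 training points per class) yields true posterior
   probabilities P(bunch | x) per point.
4. **Smooth** — the labeling energy
   E(L) = Σᵢ (1 − Pᵢ(Lᵢ)) + λ Σ_(i,j) 1[Lᵢ ≠ Lⱼ]
   over a 3 mm neighborhood graph is minimized exactly by s-t min-cut
   (binary Potts energy).
5. **Segment** — two-stage connected components (5 mm, then 1 mm for
   oversized fusions) with size filtering turns bunch points into
   candidate bunches.
6. **findBerries** — randomized sphere fitting with a four-stage candidate
   hierarchy (radius range, inlier/outlier support, the valley test using
   the nearest camera position, sphere overlap) counts and sizes the
   berries in each candidate bunch.
7. **Report** — bunches with ≥ 3 berries constitute the bunch count; berry
   count and diameter statistics are pooled, with recall / precision /
   RMSE evaluation against reference data.

A synthetic-scene generator with full ground truth (berry positions and
radii, per-point class, bunch ids, camera track) makes every stage testable
without field data.

## Worked example

```python
from vitis3d.config import PipelineConfig
from vitis3d.pipeline import run_pipeline, train_from_labeled_cloud
from vitis3d.preprocess import preprocess
from vitis3d.synthetic import SceneConfig, generate_scene

# train on one labeled row, evaluate on a fresh one
train = generate_scene(SceneConfig(seed=101, n_bunches=3, leaf_count=12,
                                   stem_count=1, row_length=0.75))
clean, _ = preprocess(train.cloud)
cfg = PipelineConfig(seed=5)
model = train_from_labeled_cloud(clean, train.cameras, cfg)

row = generate_scene(SceneConfig(seed=777, n_bunches=12, bunch_spacing=0.25,
                                 row_length=3.0, leaf_count=60, stem_count=3))
result = run_pipeline(row.cloud, row.cameras, model, cfg)
print(result.report.bunch_count, result.report.berry_count,
      round(result.report.diameter_mean * 1000, 2))
```

This prints `12 89 12.35`: all 12 bunches of the simulated row are
recovered, 89 of its 95 berries are detected (the missing ones face away
from every camera), and the mean detected diameter of 12.35 mm sits within
half a millimeter of the generator's true 12.02 mm mean.

The same pipeline is scriptable from the shell:

```bash
vitis3d simulate --out sim --seed 24 --n-bunches 2
vitis3d train sim/scene.ply sim/cameras.txt --labels sim/truth_labels.txt \
        --out model.json
vitis3d run sim/scene.ply sim/cameras.txt model.json --out results/
```

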