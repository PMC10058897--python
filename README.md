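# wound3d

Segmentation and measurement of chronic wounds from multi-view 3D scans.

Chronic wounds (pressure, venous, diabetic ulcers) are monitored through
changes in perimeter, area and volume. Given a reconstructed wound-region
point cloud (positions + unit normals) and a set of recordings — per view a
calibrated pinhole camera with optimized pose, a depth image, and a binary
wound mask registered to the depth grid — `wound3d`:

1. fuses the per-view masks onto the cloud with an occlusion-aware score
   (closer camera and more frontal surface win; views whose measured depth
   disagrees with the reprojected depth are rejected as occluded):

   `score = 1/‖P − C‖ · 1/max(θ°, 1°)`

2. triangulates the labeled cloud (greedy tangent-plane triangulation) and
   densifies it with two iterations of Midpoint subdivision;
3. refines the over-segmented mask boundary with a 3D active contour on the
   mesh graph, `E = −Σ M̂ᵢ + α Σ geodesic(pᵢ, pᵢ₊₁)/L̄ + β Σ ‖pᵢ₊₁ − 2pᵢ + pᵢ₋₁‖²/L̄²`,
   where the attraction `M̂` is the largest eigenvalue of the covariance of
   surface normals in a 5 mm ball (large on wound rims), with greedy
   per-node moves, closed-spline resampling and vertex snapping;
4. cuts the wound out along the contour, closes it with a flat virtual skin
   top (constrained Delaunay on the boundary's PCA plane), and reports
   perimeter (mm), area (mm², the skin missing over the wound), and volume
   (mm³, divergence theorem over the watertight model).

No scanner is required to use or test the package: the `phantom` module
generates synthetic craters with analytic ground truth (spherical-cap
geometry: perimeter 2πa, area πa², volume (πh/6)(3a²+h²)), rendered
depth images and corrupted masks that emulate the robot-scanner setup.

## Worked example

```python
import wound3d as w

spec = w.PhantomSpec(seed=1)                 # 10 mm aperture, 5 mm deep crater
cloud, gt = w.generate_phantom(spec)         # 4225 oriented points
recordings = w.render_views(cloud, gt, spec) # 4 views: depth + dilated masks

config = w.PipelineConfig(seed=1)            # reference defaults
seg = w.segment(cloud, recordings, config)   # fuse, mesh, subdivide, snake
report, cut = w.measure(
    seg,
    ground_truth=w.GroundTruth(perimeter=gt.perimeter, area=gt.aperture_area,
                               volume=gt.cavity_volume),
    config=config,
)
print(report.as_dict())
```

prints (values rounded):

```
{'perimeter_mm': 64.01, 'area_mm2': 316.25, 'surface_area_mm2': 391.87,
 'volume_mm3': 822.91, 'err_perimeter_pct': 1.87, 'err_area_pct': 0.67,
 'err_volume_pct': 3.28}
```

The crater's true rim is 62.83 mm around, its aperture 314.16 mm², its
cavity 850.85 mm³: the pipeline recovers them to 1.9%, 0.7% and 3.3%
despite the 2.4 mm mask over-segmentation and boundary jitter. The
`surface_area_mm2` entry is the cut wound surface proper (the cap measures
π(a²+h²) ≈ 392.7 mm²), as opposed to the flat skin-top area reported as
`area_mm2`.

The same pipeline runs from the shell:

```bash
wound3d phantom --seed 1 --out bundle/
wound3d segment bundle/cloud.ply bundle/manifest.json --out seg/
wound3d measure seg/ --ground-truth bundle/ground_truth.json --out meas/
# or all at once:
wound3d run-all --seed 1 --out run/
```

Short narrative scripts for each capability live in `examples/`.

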