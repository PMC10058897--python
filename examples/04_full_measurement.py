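"""Full pipeline on the default phantom: from recordings to a wound report.

Runs label fusion, meshing, subdivision, the active contour, the cut along
the final contour, virtual-skin-top hole filling, and the three clinical
measurements, then compares them with the crater's closed forms.
"""

import numpy as np

import wound3d as w

spec = w.PhantomSpec(seed=1)
cloud, gt = w.generate_phantom(spec)
recordings = w.render_views(cloud, gt, spec)

config = w.PipelineConfig(seed=1)
seg = w.segment(cloud, recordings, config)
print(f"mesh: {seg.mesh.vertex_count} vertices after subdivision; "
      f"contour: {seg.contour.node_count} nodes")

report, cut = w.measure(
    seg,
    ground_truth=w.GroundTruth(perimeter=gt.perimeter, area=gt.aperture_area,
                               volume=gt.cavity_volume),
    config=config,
)
print(f"perimeter : {report.perimeter:8.2f} mm   "
      f"(truth {gt.perimeter:8.2f}, error {report.errors_vs_gt['perimeter']:.2f}%)")
print(f"area      : {report.area:8.2f} mm^2 "
      f"(truth {gt.aperture_area:8.2f}, error {report.errors_vs_gt['area']:.2f}%)")
print(f"volume    : {report.volume:8.2f} mm^3 "
      f"(truth {gt.cavity_volume:8.2f}, error {report.errors_vs_gt['volume']:.2f}%)")
print(f"wound surface area proper: {report.surface_area:.2f} mm^2 "
      f"(cap surface = pi(a^2+h^2) = {np.pi * 125:.2f})")
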