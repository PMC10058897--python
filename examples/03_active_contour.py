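"""Watch the 3D active contour find a hole rim on a synthetic surface.

The surface is a plate with a steep-walled circular depression; the snake
starts on the over-segmented label boundary 3 mm outside the rim and is
pulled onto the rim by the normal-covariance curvature field, while spline
resampling keeps it smooth. The energy breakdown is printed per iteration.
"""

import numpy as np
from scipy.spatial import cKDTree

import wound3d as w

mesh, rim = w.make_hole_mesh(outer_radius=20.0, hole_radius=10.0, depth=5.0,
                             spacing=0.5, label_margin=3.0)
graph = w.build_mesh_graph(mesh)
contour = w.extract_initial_contour(mesh)
r0 = np.hypot(contour.positions[:, 0], contour.positions[:, 1]).mean()
print(f"initial contour: {contour.node_count} nodes at mean radius {r0:.2f} mm "
      "(true rim at 10.00 mm)")

final, trace = w.run_acm(contour, w.ACMConfig(iterations=10), graph=graph)
for i, e in enumerate(trace, 1):
    print(f"iter {i:2d}: E_total={e.total:9.2f}  attraction={e.mesh:9.2f}  "
          f"elastic={e.elastic:7.2f}  smooth={e.smooth:7.2f}")

r = np.hypot(final.positions[:, 0], final.positions[:, 1])
d, _ = cKDTree(mesh.vertices[rim]).query(final.positions)
print(f"final contour: mean radius {r.mean():.2f} mm, "
      f"mean distance to tagged rim {d.mean():.3f} mm")
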