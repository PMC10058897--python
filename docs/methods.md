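# Methods

`wound3d` measures chronic wounds from multi-view 3D scans. Its input is
the output of a scanning rig: a reconstructed point cloud of the wound
region with per-point unit normals, and a set of recordings, each a
calibrated pinhole camera with an optimized pose, a depth image on that
camera's pixel grid, and a binary wound mask registered to the same grid
(produced upstream by a 2D segmentation front end and deliberately
over-segmented by a 30 px dilation to absorb calibration and segmentation
error). All geometry is in millimetres.

## Pipeline

1. **Label fusion.** Every cloud point is reprojected into every view.
   A view is usable for a point when the point is in frame, the surface
   faces the camera (normal/view-axis angle ≤ 90°), the sensor depth at the
   pixel is valid, and the sensor depth agrees with the reprojected depth
   within a tolerance (default 5 mm) — disagreement means another surface
   occludes the point in that view. Among usable views the one with the
   highest score

       score = 1 / ‖P − C‖ · 1 / max(θ°, 1°)

   donates its mask value (P point, C camera center, θ the angle between
   the surface normal and the reverse viewing axis, clamped at 1° to avoid
   the frontal singularity; ties go to the lower view index). Points with
   no usable view are labeled non-wound.

2. **Meshing.** The labeled cloud is triangulated by a greedy
   projection-style algorithm: each point projects its radius neighborhood
   (3 × mean nearest-neighbor spacing, ≤ 100 neighbors, normals within 60°
   of the seed normal) onto its tangent plane, triangulates it in 2D, and
   votes for the triangles incident to itself; triangles confirmed by at
   least two of their vertices are kept under an orientability guard (each
   undirected edge carries at most two triangles, traversed in opposite
   directions). Neighbor lists are put in canonical (index) order before
   each local triangulation so cocircular configurations resolve
   identically in every neighborhood. The guard rejects the rare crisscross
   overlaps that would otherwise create slits and non-orientable
   micro-handles; the small holes it leaves instead are covered during
   measurement. The 60° normal cutoff must exceed the crease angle at the
   wound rim — a spherical-cap crater of aperture radius a and depth h
   meets the skin at asin(2ah/(a²+h²)), 53° for the typical a = 2h — or the
   mesh cracks along every deep rim.

3. **Initial contour.** The boundary edges of the wound-labeled submesh
   are chained into closed loops; the longest loop, subsampled to every
   second vertex, is the snake's initial contour. Extraction happens at
   acquisition resolution, before subdivision, which gives the snake
   workable node spacing (≈ 1 mm here; extracting after subdivision gives
   0.23 mm spacing and a jitter-dominated loop).

4. **Subdivision.** Two iterations of Midpoint subdivision (each triangle
   → 4 coplanar children, edge midpoints created once per shared edge,
   geometry and total area unchanged, labels propagate conservatively by
   AND). Densification gives each snake node more candidate vertices per
   move. Original vertex indices are preserved, so the initial contour
   remains valid on the refined mesh.

5. **Active contour.** The mesh induces an edge-weighted graph (vertices,
   triangle edges, Euclidean lengths). The per-vertex attraction field is
   the largest eigenvalue of the mean-centered covariance of unit normals
   in a 5 mm Euclidean ball (flat → 0, crease → large, peaking where the
   ball balances the two normal populations, i.e. at the rim). The total
   energy of an n-node contour is reported as

       E_total = E_mesh + α E_elastic + β E_smooth
       E_mesh    = −Σ M̂(p_i)                       (curvature, max-normalized)
       E_elastic = Σ geodesic(p_i, p_{i+1}) / L̄     (graph geodesics)
       E_smooth  = Σ ‖p_{i+1} − 2p_i + p_{i−1}‖² / L̄²

   with α = β = 1 and L̄ the mean mesh edge length. One iteration: each
   node gathers its 2-ring, greedily moves to the candidate minimizing its
   local energy with neighbors at pre-update positions, a periodic cubic
   spline (chord-length parameterized) is fit through the new positions,
   resampled uniformly in arc length at the same node count, and each
   sample snaps to the nearest mesh vertex. Ten iterations by default.

   *Greedy normalization.* In the greedy step the elastic and smoothing
   contributions are expressed as the node's share of the whole-contour
   energy (divided by n·ℓ̄ and n·ℓ̄², ℓ̄ the mean segment chord). This makes
   the curvature attraction the leading term of each move while the contour
   terms break ties among near-equal-curvature candidates; regularity is
   chiefly enforced by the spline resampling. The choice is deliberate and
   load-bearing: if the contour terms are normalized to the same per-move
   scale as the attraction (per mesh edge, per candidate window, or raw
   millimetres), a single-node move of one edge costs an order of magnitude
   more smoothing penalty than it gains attraction, and the snake freezes —
   measured drifts of 0.006–0.04 mm per iteration against the ≈ 0.25 mm
   per iteration needed to traverse the mask over-segmentation within ten
   iterations. With unit weights and the per-node-share scales the snake
   contracts onto the rim and the energy trace decreases essentially
   monotonically.

6. **Cut, fill, measure.** Consecutive contour nodes are joined by their
   geodesic vertex paths into one closed polyline (the barrier), which is
   spliced free of short zigzag pockets and straightened by a taut-band
   relaxation (replacing lattice detours by shorter single-vertex bridges —
   raw graph geodesics zigzag and the resulting dips into the cavity bias
   the enclosed volume low). Interior holes of the mesh are covered first
   and the cut graph rebuilt, because a barrier running along a hole rim
   does not separate the surface. The wound side is selected by a two-sided
   competitive flood seeded from the faces left and right of the oriented
   barrier, which tolerates residual genus defects of the reconstruction.
   Boundary loops of the cut are closed with planar covers (constrained 2D
   Delaunay on each loop's PCA plane; GEOS adds no Steiner points, so
   covers lift back exactly onto loop vertices). The **virtual skin top** —
   the cover over the contour loop, representing the missing skin — is
   built flat *on* the PCA plane, joined to the on-surface loop by a thin
   skirt; a cover interpolated through the warped 3D loop would hang from
   the loop's lowest vertices and bias the volume (−8% measured on the
   default phantom). Reported quantities:

   * **perimeter** — chordal sum between consecutive contour nodes
     (default). Graph-geodesic sums are available as a mode but
     overestimate a smooth boundary by the lattice's spanner ratio (≈ 13%
     measured at 0.15 mm edges), which is incompatible with the few-percent
     perimeter accuracy the approach achieves otherwise.
   * **area** — the flat skin-top area (degenerates to the surface area for
     flat wounds); the wound surface area proper is reported alongside.
   * **volume** — divergence-theorem volume of the watertight union
     (orientation fixed outward first), absolute value. Wounds with less
     than 1 mm of relief below the skin plane are reported flat, with no
     volume.

## Synthetic phantoms

The generator builds a skin patch (plane or cylinder patch) with a
spherical-cap crater: aperture radius a, depth h ≤ a, closed forms
perimeter 2πa, aperture area πa², cavity volume (πh/6)(3a² + h²). Default
conditions: a = 10 mm, h = 5 mm, jittered-grid sampling at 0.5 mm, 0.02 mm
Gaussian position noise, analytic outward normals. Four views on a ring
25° off vertical at 200 mm working distance render depth images by
point-splat z-buffering (1 px footprint) at 768² px with f = 2500 px
(≈ 0.08 mm/px on the surface); masks are the splatted projections of the
true wound points, dilated 30 px (≈ 2.4 mm of over-segmentation, the
few-millimetre scale of the calibration error that dilation guards
against) and boundary-jittered 2 px. Optional occluder discs overwrite
nearer depths in chosen views to exercise the occlusion test. All
randomness flows from one integer seed; outputs are bitwise reproducible.

A second generator builds the classic snake test surface: a plate with a
steep-walled cylindrical depression, rim vertices tagged, labels emulating
a dilated mask.

What the phantoms do **not** emulate: real 2D-segmentation error structure
(only dilation + jitter), specular or low-reflectance scan dropout, pose
error in the optimized camera poses, multi-wound scenes, tunneling, and
strongly non-height-field geometry. Passing the phantom suite therefore
shows the geometry pipeline is correct and accurate under scanner-like
sampling; it does not validate the upstream 2D segmenter or reconstruction.

## Numerical choices

* Curvature neighborhoods use Euclidean balls; covariance is mean-centered;
  on very dense (subdivided) meshes the neighbor pool is thinned by a
  deterministic stride to ≈ 600 expected points per ball. Vertices with
  < 3 in-ball neighbors get value 0 (warning logged).
* Greedy ties: the current vertex wins, then the lowest index; nearest-
  vertex snapping breaks exact distance ties toward the lowest index.
* Spline fits merge consecutive duplicate points, use k=3 (k=1 below 4
  distinct points) and explicit closure; arc-length resampling inverts the
  cumulative chord length of a 25× dense evaluation.
* Duplicate consecutive snapped nodes are kept (node count is invariant);
  they contribute zero length.
* Covers: a cover diagonal coinciding with a surface edge is split at its
  midpoint (zero geometric change) to keep every edge on exactly two
  triangles; pinched (figure-eight) hole loops fall back to quality-first
  ear clipping, and their degenerate zero-area triangles are tolerated in
  covers only. A self-intersecting *contour* projection is an error unless
  the crossing is hairline (repaired area within 2%).
* The per-run problem size (≈ 4.2 k points, ≈ 133 k triangles after
  subdivision, ≈ 45 s end to end) was chosen so the full default phantom
  pipeline and its closed-form checks run comfortably on one CPU.

## Known limitations

* Shallow wounds with pronounced top and bottom borders can make the snake
  slip to the nearer (bottom) border and under-segment — the attraction
  field cannot distinguish the two when the wound depth is comparable to
  the curvature radius.
* A neighboring wound's stronger rim inside the mask region can capture
  part of the contour.
* The triangulator assumes scanner-like, roughly even sampling; strongly
  uneven or multi-layer clouds are out of scope.
* Perimeter/area/volume accuracy is bounded by vertex quantization of the
  cut (≈ one subdivided edge, 0.15 mm here) and by the flat-skin-top
  approximation for wounds whose true skin is strongly curved; the
  cylinder-patch base exists to study the latter.
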