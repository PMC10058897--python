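dilation_radius_px: 30
depth_tolerance_mm: 5.0
voxel_size_mm: null
gpt_search_radius_factor: 3.0
gpt_max_neighbors: 100
gpt_max_surface_angle_deg: 60.0
subdivision_iterations: 2
curvature_radius_mm: 5.0
alpha: 1.0
beta: 1.0
neighborhood_hops: 2
acm_iterations: 10
perimeter_mode: chord
flat_threshold_mm: 1.0
seed: 0
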