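# capsim run configuration (versioned schema)
version: 1
seed: 1

grid:
  nodes_per_side: 200
  side_length: 1000.0      # um
  capsule_radius: 350.0    # um

transport:
  D_medium: 0.15           # um^2/s
  cell_ratio: 100.0        # D_cell = D_medium / cell_ratio
  C_inj: 13.0              # ug/mL, exterior bath concentration
  interface_mode: harmonic

saturation:
  a: 1.0
  n: 1.0
  p: 1.0
  saturation_fraction: 0.01
  dt_ref: 120.0            # s

simulation:
  total_time_min: 180.0
  frame_interval_min: 2.0
  cfl_safety: 0.5
  saturation_enabled: true

# exactly one of `placement` (stochastic capsule) or `mask` (digitized)
placement:
  n_spheroids: 1
  spheroid_radius: 50.0
  n_fibro_single: 30
  fibro_single_radius: 11.5
  n_fibro_cluster: 8
  fibro_cluster_radius: 17.5
  outer_ring_fraction: 0.2
  outer_ring_prob: 0.7
  n_fibers: 25
  fiber_length: 30.0
  fiber_orientations: [0, 45, 90, 135]

# mask:
#   path: capsule_mask.png
#   spheroids:                # manual cancer-spheroid additions
#     - center: [704.0, 434.0]
#       radius: 50.0

rois:
  - id: cluster1
    center: [704.3, 434.3]
    radius: 50.0
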