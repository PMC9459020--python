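# Camera-type eye by fusion of many tightly seeded units into one retina.
# Default is the late_fusion variant (exclusion 1); early_fusion uses 0.8.
name: one_eye_fusion
min_cell_count: 5000
avg_cell_size: 10
cell_size_variance: 2
cell_max_size: 15
cell_growth_rate: 0.005
furrow_velocity: 20
simulation_speed: 100
founder:
  exclusion_radius: 1
  target_radius: 10
  min_distance_from_edge: 8
  distance_from_furrow: 0
waves:
  - {selection_count: 2, target_radius: 20, max_distance_from_r8: 2, distance_from_furrow: 100}
  - {selection_count: 2, target_radius: 25, max_distance_from_r8: 2, distance_from_furrow: 200}
  - {selection_count: 2, target_radius: 25, max_distance_from_r8: 4, distance_from_furrow: 300}
border:
  border_radius: 1
  target_radius: 20
  distance_from_furrow: 400
death:
  death_chance: 20
  distance_from_furrow: 1000
variants:
  early_fusion:
    founder: {exclusion_radius: 0.8}
  late_fusion:
    founder: {exclusion_radius: 1}
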