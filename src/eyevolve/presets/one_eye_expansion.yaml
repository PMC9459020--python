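# Camera-type eye by expansion: a single founder recruits concentric PR rings.
name: one_eye_expansion
min_cell_count: 5000
avg_cell_size: 10
cell_size_variance: 2
cell_max_size: 15
cell_growth_rate: 0.005
furrow_velocity: 20
simulation_speed: 100
founder:
  exclusion_radius: 40
  target_radius: 10
  min_distance_from_edge: 30
  distance_from_furrow: 0
waves:
  - {selection_count: 800, target_radius: 20, max_distance_from_r8: 600, distance_from_furrow: 400}
  - {selection_count: 800, target_radius: 25, max_distance_from_r8: 500, distance_from_furrow: 800}
  - {selection_count: 800, target_radius: 25, max_distance_from_r8: 600, distance_from_furrow: 1000}
border:
  border_radius: 1
  target_radius: 20
  distance_from_furrow: 2000
death:
  death_chance: 20
  distance_from_furrow: 2200
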