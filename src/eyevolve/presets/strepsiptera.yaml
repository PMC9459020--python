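# Twisted-wing insect "chunk vision": widely spaced, enlarged image-forming units.
name: strepsiptera
min_cell_count: 7000
avg_cell_size: 10
cell_size_variance: 2
cell_max_size: 15
cell_growth_rate: 0.005
furrow_velocity: 20
simulation_speed: 100
founder:
  exclusion_radius: 10
  target_radius: 10
  min_distance_from_edge: 10
  distance_from_furrow: 0
waves:
  - {selection_count: 35, target_radius: 20, max_distance_from_r8: 50, distance_from_furrow: 100}
  - {selection_count: 35, target_radius: 20, max_distance_from_r8: 50, distance_from_furrow: 200}
  - {selection_count: 35, target_radius: 20, max_distance_from_r8: 50, distance_from_furrow: 300}
border:
  border_radius: 2
  target_radius: 20
  distance_from_furrow: 400
death:
  death_chance: 20
  distance_from_furrow: 1000
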