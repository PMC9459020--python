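# Insect median ocelli: few large units, 150+150+150 photoreceptors each.
name: ocelli
min_cell_count: 10000
avg_cell_size: 10
cell_size_variance: 2
cell_max_size: 25
cell_growth_rate: 0.01
furrow_velocity: 10
simulation_speed: 10
founder:
  exclusion_radius: 28
  target_radius: 20
  min_distance_from_edge: 25
  distance_from_furrow: 0
waves:
  - {selection_count: 150, target_radius: 30, max_distance_from_r8: 200, distance_from_furrow: 100}
  - {selection_count: 150, target_radius: 30, max_distance_from_r8: 200, distance_from_furrow: 150}
  - {selection_count: 150, target_radius: 30, max_distance_from_r8: 200, distance_from_furrow: 200}
border:
  border_radius: 5
  target_radius: 15
  distance_from_furrow: 550
death:
  death_chance: 10
  distance_from_furrow: 600
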