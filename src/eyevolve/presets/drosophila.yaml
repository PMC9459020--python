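# Fruit-fly compound eye: many tightly spaced ommatidia, 2+2+2 photoreceptors.
name: drosophila
min_cell_count: 10000
avg_cell_size: 8
cell_size_variance: 0.1
cell_max_size: 15
cell_growth_rate: 0.005
furrow_velocity: 20
simulation_speed: 100
founder:
  exclusion_radius: 2
  target_radius: 20
  min_distance_from_edge: 3
  distance_from_furrow: 0
waves:
  - {selection_count: 2, target_radius: 20, max_distance_from_r8: 2, distance_from_furrow: 100}
  - {selection_count: 2, target_radius: 20, max_distance_from_r8: 2, distance_from_furrow: 150}
  - {selection_count: 2, target_radius: 25, max_distance_from_r8: 4, distance_from_furrow: 200}
border:
  border_radius: 1
  target_radius: 20
  distance_from_furrow: 1000
death:
  death_chance: 30
  distance_from_furrow: 1200
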