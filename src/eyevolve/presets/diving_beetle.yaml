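# Dytiscus larva: a cluster of six medium image-forming stemmata.
# (The 100-count middle wave breaks the 50/100/50 symmetry; carried verbatim.)
name: diving_beetle
min_cell_count: 7000
avg_cell_size: 10
cell_size_variance: 2
cell_max_size: 15
cell_growth_rate: 0.005
furrow_velocity: 20
simulation_speed: 100
founder:
  exclusion_radius: 25
  target_radius: 10
  min_distance_from_edge: 13
  distance_from_furrow: 0
waves:
  - {selection_count: 50, target_radius: 20, max_distance_from_r8: 50, distance_from_furrow: 200}
  - {selection_count: 100, target_radius: 18, max_distance_from_r8: 50, distance_from_furrow: 400}
  - {selection_count: 50, target_radius: 20, max_distance_from_r8: 80, distance_from_furrow: 600}
border:
  border_radius: 2
  target_radius: 20
  distance_from_furrow: 800
death:
  death_chance: 20
  distance_from_furrow: 1000
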