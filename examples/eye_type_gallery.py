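"""Different eye types from one developmental program.

Runs the two small published presets — butterfly-larva stemmata (1,000
cells) and diving-beetle larval eyes (7,000 cells) — and prints the unit
census of each: same rules, very different eyes, changed only by the input
parameters.
"""

from eyevolve import generate_epithelium, load_preset, render_snapshot, run_simulation
from eyevolve.metrics import census, unit_count

for name in ("lepidoptera_larva", "diving_beetle"):
    params = load_preset(name)
    ep = generate_epithelium(params.min_cell_count, params.avg_cell_size,
                             params.cell_size_variance, seed=1)
    state = run_simulation(params, ep, seed=1)
    print(f"\n{name}: {unit_count(state)} eye units "
          f"from {params.min_cell_count} precursors")
    for c in census(state):
        waves = tuple(c.counts.get(f"PR_WAVE{k}", 0) for k in (1, 2, 3))
        print(f"  unit {c.unit_id}: waves {waves}, "
              f"{c.counts.get('BORDER', 0)} border cells")
    render_snapshot(state, f"{name}.png")
    print(f"  wrote {name}.png")
# Lepidoptera larvae carry ~6 small, widely spaced stemmata (2+2+2 PRs);
# the beetle's six larval eyes each hold 200 photoreceptors (50+100+50).
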