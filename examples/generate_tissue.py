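"""Generate and inspect a precursor epithelium.

Builds a 500-cell sheet of undifferentiated circular cells (mean radius 10,
size jitter 2), relaxes it until overlaps are resolved, and saves both the
cell table and a PNG snapshot.
"""

from eyevolve import generate_epithelium, render_snapshot, save_epithelium

ep = generate_epithelium(min_cell_count=500, avg_cell_size=10,
                         cell_size_variance=2, seed=1)

report = ep.last_relax
print(f"cells:              {ep.n_alive}")
print(f"domain:             {ep.domain.width:.0f} x {ep.domain.height:.0f} world units")
print(f"relax iterations:   {report['iterations']}")
print(f"max overlap depth:  {report['max_overlap']:.3f} (tolerance 0.5)")

save_epithelium(ep, "tissue_500.csv")
render_snapshot(ep, "tissue_500.png")
print("wrote tissue_500.csv and tissue_500.png")
# The overlap depth is the worst pairwise intrusion r_i + r_j - distance:
# once below tolerance the sheet is a valid packed monolayer.
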