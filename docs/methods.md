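# Methods

## The model

The simulator reduces early eye development to five coupled processes on a
two-dimensional sheet of circular cells: (1) proliferation of an
undifferentiated precursor pool, (2) posterior-to-anterior sweep of a
morphogenetic furrow that timestamps differentiation, (3) selection of
regularly spaced founder photoreceptors (R8-like), (4) distance-limited
recruitment of further photoreceptor waves and border/support cells around
each founder, and (5) apoptotic pruning of whatever stays undifferentiated.
Gene-network dynamics (the retinal determination network, Notch/EGFR
signalling) are deliberately abstracted into the distance and count
parameters: the model asks what layouts the *geometry* of these rules can
produce, not how the signalling produces the rules.

Each cell carries a position, radius, fate (precursor, founder, one of
three wave fates, or border), a fate-specific target radius, and a unit
membership.  Fate transitions are monotone: a precursor differentiates at
most once and never reverts.  The tissue is off-lattice; neighborhood
relations are geometric (contact, Delaunay, or metric radius).

## Mechanics

**Packing and relaxation.**  Cells are seeded on a jittered square grid
sized to hold the requested count at the mean radius and relaxed with
linear pair springs.  Per iteration, an overlapping pair's separation
grows by `k_rep · (r_i + r_j − d)` and a pair with a gap above
`gap_threshold` (within twice that range) closes by
`k_att · (gap − gap_threshold)`; displacements accumulate per cell.
Defaults: `k_rep = 0.5`, `k_att = 0.02`, `gap_threshold = 0.5·avg_cell_size`,
overlap tolerance `0.05·avg_cell_size`.  The attraction constant is kept
an order of magnitude below repulsion: at `k_att ≈ 0.05` boundary cohesion
balances repulsion at a standing overlap of about `0.6` world units, which
never meets tolerance; at `0.02` dense tissues converge in under a hundred
iterations and still stay cohesive.  Neighbor pairs come from a k-d tree;
during long relaxations the pair list is refreshed every few iterations
(displacements per iteration are far smaller than the interaction margin,
so a slightly stale list only saves time).  Coincident centers break
symmetry along a fixed axis, which keeps runs reproducible.

**The domain is the initial footprint.**  Generation clamps cell centers
into the rectangle; simulation-time relaxation does not.  As specified
cells grow toward targets three to four times their initial area and
precursors keep dividing, the sheet must expand — pinning it into the
initial rectangle compresses every distance (including founder spacing) by
the square root of the area excess and contradicts behaviors the model is
supposed to show, such as units drifting apart under delayed death.  The
furrow geometry, edge margins and event offsets are all anchored to the
initial domain.

**Growth and division.**  Precursors grow by `(1 + rate)` per cycle; when
uncapped growth would exceed `cell_max_size`, the cell divides into two
daughters of radius `max/√2` (the area of a cap-sized parent is conserved)
displaced along a random axis.  Specified cells grow toward their own
target radius and never divide.  A specified cell whose current radius
already exceeds its fate's target keeps its radius (targets never shrink a
cell).

**Furrow events.**  The furrow advances `furrow_velocity` per cycle.  An
event with offset `Δ` is delivered, once per cell, to cells at
`x ≥ furrow.x + Δ`; on a static tissue this is exactly the velocity-wide
band swept that cycle.  Delivery is tracked per cell and event kind rather
than by the band's upper edge because the growing sheet can drift leftward
faster than a slow furrow (ocelli preset, velocity 10), and a strict band
would then skip cells permanently — observed as late units missing their
second and third waves before this choice was made.  Within a cycle,
events fire in ascending offset order (founder selection at offset 0
first, death last).  Wave and border events are dispatched per *unit*:
a unit fires when its founder enters the event's region.

**Founder selection** is greedy, following minimal-distance-to-existing
spacing: among precursors in the day's band that keep the required clear
spacing to every founder and the required margin to every edge of the
initial domain, repeatedly take the candidate whose minimum distance to
the current founder set is smallest (ties to the lowest cell id); if no
founder exists yet, seed with the eligible cell nearest the right
(posterior) edge.  Selection is pure; the furrow dispatch applies the fate
change and opens the unit.

**Wave recruitment.**  Candidates are precursors behind the furrow within
`max_distance_from_R8` of the founder; each unit takes its
`selection_count` nearest (ties by id), fewer if the pool is smaller.
When several units fire in one cycle, a cell in range of more than one is
*contested* and goes to the nearest founder (ties to the lower unit id).
Restricting candidates to the furrow's wake reflects that differentiation
happens behind the front; it also prevents large-radius presets from
draining the undeveloped anterior field.

**Border recruitment** wraps each unit in `border_radius` concentric
layers: layer 1 is the precursor contact ring of the unit's specified
cells, layer k the ring of layer k−1.  Contested layer cells join the
nearer founder's unit.

**Apoptosis** removes each precursor behind the death offset independently
with probability `death_chance/100` per cycle; specified cells never die.
A `one_shot` flag restricts each cell to a single lifetime draw, for
studying the alternative reading of the parameter.

**Completion and settling.**  After the furrow clears the tissue, cycles
continue until every specified cell has reached its target radius *and*,
when the hazard is nonzero, the remaining precursors have been pruned
(long sweeps finish growth mid-run, and exiting early would leave tens of
thousands of undifferentiated cells in the "final" tissue).  The run ends
with a settling relaxation (default cap 4,000 iterations, `k_rep = 0.8`,
pair refresh every 5): growth outpaces the four relaxation iterations per
cycle, leaving a compressed transient whose expansion is boundary-limited
and therefore slow; the moderately larger step — still below the per-pair
overshoot limit of 1 — accelerates it without scrambling unit geometry
(a trial with `k_rep = 1.5` recovered overlap fastest but shuffled members
between units and destroyed founder spacing for presets with small
founders, and was rejected).

## Parameter units

The published parameter table mixes magnitudes (exclusion radius 0.8–40,
cell sizes 8–10, wave distances 2–600, furrow offsets 100–2,200).  One
convention makes every column geometrically sensible, and it is
centralized in `specification.distance_to_world` / `exclusion_to_world`:

* `r8 exclusion radius` — **clear spacing** between founder cells, in mean
  cell diameters.  Eligibility threshold on centers:
  `(value + 1) · 2 · avg_cell_size`.  Sub-diameter values (0.8/1 in the
  fusion presets) then mean founders nearly touching, never coincident,
  and a center-to-center distance of at least `value` diameters follows
  a fortiori.
* `min distance from edge`, `max distance from R8` — center distances in
  mean cell diameters (`value · 2 · avg_cell_size`).
* `distance from furrow`, `furrow velocity` — raw world units.

Under this reading the presets reproduce the published layouts — complete
2+2+2 ommatidia under the fly preset, a handful of spaced stemmata with
full photoreceptor complements (`examples/eye_type_gallery.py` prints
their censuses), 450-photoreceptor ocellus units and 35-per-wave
Strepsiptera units (census tests), exactly one expansion founder with a
concentric profile, and a fused mosaic with interleaved receptor types
(regime tests).  A plain center-to-center reading was implemented first;
it starved most units (the per-unit pool shrinks quadratically with
founder spacing) and left the fusion retina without later wave types, so
the clear-spacing reading was adopted.  The conversion lives in one
function and can be swapped.

## Simulation speed

`simulation_speed` (cycles per second) throttles interactive display
only; headless runs carry the value but ignore it, since it cannot affect
results.

## Randomness and reproducibility

One root seed spawns independent child streams per consumer (generation,
growth/division, founder ties, waves, death), so adding an event kind
does not perturb the draws of the others.  Identical (epithelium file,
parameters, seed) produce byte-identical final cell tables; the event log
(JSON-lines of every founder/wave/border/death/division mutation with its
cycle) makes runs auditable.  Relaxation is deterministic and unlogged;
replay therefore means rerunning, not log application.

## Metrics

* **census** — per-unit fate counts plus founder position, centroid and
  unit radius; the conservation identity
  `initial + divisions − removals = alive` is checked against the log.
* **founder_spacing** — min/mean pairwise distance and the coefficient of
  variation of nearest-neighbor distances; cv 0 is a perfect lattice,
  ~0.5 Poisson seeding.  Chosen over Fourier-type hexagonality scores as
  the simplest statistic separating a "roughly hexagonal" array from
  random placement that is also exactly testable on constructed lattices.
* **wave_radial_profile** — per-wave mean member distance to founder;
  strictly increasing for expansion-built eyes.
* **wave_label_assortativity** — Pearson correlation of recruitment-order
  labels over contact pairs of photoreceptors, founders included as label
  0 (the mosaic claim concerns receptor types, of which the founder is
  one); near 1 for concentric retinas, near 0 for fused mosaics.  A
  waves-only variant is available.

## What the tests do and do not show

Test tissues are generated by the package itself (grids, hexagonal
patches, strips, relaxed random sheets), so every geometric oracle is
exact; there is no measurement noise, no real imaging, and no biological
variation beyond the seeded size jitter and death lottery.  Passing tests
show that the implementation realizes the stated rules and that the rules
reproduce the published counts and spacings — not that real eye discs
follow these rules.  In particular the model is 2-D (no Semper cells, no
R7), has no cell adhesion (specified cells can be nudged off their units
during vigorous expansion, visible as imperfect lattices), one border
cell type, and a furrow that is always a vertical line.

## Problem sizes

The test suite runs the published tissue sizes where the claim depends on
them (10,000-cell generation; full-scale ocelli and Strepsiptera censuses)
and half-scale epithelia for the cross-preset founder-spacing sweep and
the Drosophila spacing quantity, where the bound is scale-free; the
monotonicity property uses the published 5,000-cell setting with five
seeds.  The acceptance script states each run's size in its output
(`"n"`).
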