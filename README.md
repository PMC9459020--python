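# eyevolve

An agent-based simulator of arthropod eye development.  A virtual
morphogenetic furrow (MF) sweeps a two-dimensional epithelium of circular
precursor cells from posterior (right) to anterior (left); distance-gated
events behind the furrow specify equally spaced founder photoreceptors
(R8-like cells), recruit three sequential photoreceptor waves (the R2/R5-,
R3/R4- and R1/R6-like pairs of the fly) plus layers of border/pigment
cells around each founder, and prune the remaining undifferentiated cells
by apoptosis.  Changing a handful of parameters — precursor pool size,
founder exclusion radius, per-wave selection counts, border layers, death
chance — moves the outcome between a compound eye of hundreds of
ommatidia, a few widely spaced stemmata, large ocellus-like units, and
single-chamber eyes built either by *expansion* of one unit or *fusion*
of many.

It is written for developmental and evolutionary biologists who want to
ask "which minimal parameter changes turn one eye layout into another?"
without modelling the underlying gene networks explicitly.

## Model in brief

* **Epithelium** — `n` circular cells with radii `r ~ N(μ, σ)` packed into a
  square initial domain and relaxed with linear pair springs: overlapping
  pairs repel along their center line with step `k_rep·(r_i + r_j − d)`,
  near pairs with a gap above a threshold attract weakly (`k_att`).
* **Furrow** — a vertical line at `x(t) = x_max − v·t`.  An event with
  offset `Δ` acts on cells at `x ≥ x(t) + Δ` exactly once per cell
  (apoptosis instead re-draws each cycle).
* **Founder selection** — greedy: among band precursors at least
  `min_distance_from_edge` from the tissue edge and leaving at least the
  `exclusion radius` of clear spacing to every existing founder, repeatedly
  take the candidate closest to the current founder set (posterior-most
  cell first).
* **Waves** — each unit recruits its `selection_count` nearest precursors
  within `max_distance_from_R8`; contested cells go to the nearest founder.
* **Borders** — `border_radius` concentric contact layers around the
  unit's specified core.
* **Death** — every undifferentiated cell behind the death offset dies
  with probability `death_chance/100` per cycle.
* **Growth** — precursors grow multiplicatively and divide (area
  conserved) at `cell_max_size`; specified cells grow to their fate's
  target radius and never divide.

Distance-like founder/wave parameters are in units of the mean cell
diameter (`2·avg_cell_size`); furrow offsets and velocities are world
units.  See `docs/methods.md` for the full parameter table semantics,
numerical choices and limitations.

## Worked example

```sh
python examples/eye_type_gallery.py
```

```
lepidoptera_larva: 7 eye units from 1000 precursors
  unit 0: waves (2, 2, 2), 10 border cells
  unit 1: waves (2, 2, 2), 13 border cells
  unit 2: waves (2, 2, 2), 11 border cells
  ...
  wrote lepidoptera_larva.png

diving_beetle: 8 eye units from 7000 precursors
  unit 0: waves (50, 100, 50), 121 border cells
  unit 1: waves (50, 100, 50), 127 border cells
  ...
  wrote diving_beetle.png
```

The butterfly-larva preset yields ~6–7 small, widely spaced
ommatidium-like stemmata with the full 2+2+2 photoreceptor complement;
the diving-beetle preset yields a cluster of larger image-forming eyes,
each with its 50+100+50 photoreceptors — the same program, different
parameters.  `examples/expansion_vs_fusion.py` contrasts the two
single-chamber routes: the expansion run prints a strictly increasing
per-wave radial profile (concentric rings) while late fusion prints a
receptor-type spatial autocorrelation near zero (an interleaved mosaic).

## Command line

```sh
eyevolve generate --cells 5000 --seed 1 --out tissue.csv
eyevolve run --preset drosophila --seed 1 --out out/      # full run + manifest
eyevolve run --config my_params.yaml --epithelium tissue.csv --out out2/
eyevolve metrics --cells out/cells.csv --out metrics.csv
eyevolve render --cells out/cells.csv --out eye.png
```

Every run directory contains the initial and final cell tables, a
JSON-lines event log, per-unit metrics, a summary JSON and a manifest
(parameters + seed + version); identical manifests reproduce byte-identical
cell tables.  Saved epithelia can be reused so different presets start
from the same tissue.

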