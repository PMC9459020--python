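"""Differentiation events fired behind the furrow.

Four events turn precursors into eye-unit cells:

* founder selection — greedy, exclusion-radius-spaced seeding of R8-like
  cells, the organizing center of each unit;
* photoreceptor waves — each unit recruits its ``selection_count`` nearest
  precursors within range, in three sequential waves;
* border recruitment — concentric contact layers of support cells around a
  unit's specified core;
* apoptosis — a per-cycle death lottery for precursors left behind.

Unit convention: ``min_distance_from_edge`` and ``max_distance_from_r8``
are center distances in mean cell diameters (:func:`distance_to_world`);
``exclusion_radius`` is clear spacing between founders
(:func:`exclusion_to_world`); furrow offsets are raw world units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .epithelium import Epithelium, Fate, ParameterError, WAVE_FATES
from .params import BorderParams, DeathParams, FounderParams, WaveParams


def distance_to_world(value: float, ep: Epithelium) -> float:
    """Convert a distance parameter (cell diameters) to world units.

    The single place the unit convention lives; swap here to change it.
    """
    return float(value) * 2.0 * ep.avg_cell_size


def exclusion_to_world(value: float, ep: Epithelium) -> float:
    """Center-to-center eligibility threshold for the founder exclusion radius.

    The exclusion radius is the *clear* spacing between founder cells, in
    mean-diameter units; for average-size cells a clear gap of ``value``
    diameters means centers at least ``(value + 1)`` diameters apart.  This
    reading keeps sub-diameter Table values (0.8, 1 in the fusion presets)
    physically meaningful — founders nearly touching, never coincident — and
    implies the weaker center-distance bound value * 2 * avg_cell_size.
    """
    return (float(value) + 1.0) * 2.0 * ep.avg_cell_size


@dataclass
class EyeUnit:
    """A founder cell plus everything it recruited."""

    unit_id: int
    founder_id: int
    members: dict[int, list[int]] = field(default_factory=lambda: {1: [], 2: [], 3: []})
    border_ids: list[int] = field(default_factory=list)

    @property
    def specified_ids(self) -> list[int]:
        out = [self.founder_id]
        for k in (1, 2, 3):
            out.extend(self.members[k])
        return out

    @property
    def all_ids(self) -> list[int]:
        return self.specified_ids + list(self.border_ids)


# ---------------------------------------------------------------------------
# founder selection


def select_founders(
    band_cells,
    existing_founders,
    fp: FounderParams,
    ep: Epithelium,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Greedily choose new founder cells from a furrow band.

    Eligibility: a precursor leaving at least ``exclusion_radius`` clear
    spacing to every existing founder (see :func:`exclusion_to_world`) and at
    least ``min_distance_from_edge`` (cell diameters) to every domain edge.
    While eligible candidates remain, the one with the smallest
    minimum distance to the current founder set is taken (ties by lowest id);
    the very first founder is the eligible cell nearest the right domain edge,
    mirroring posterior-first differentiation.  Pure selection: the caller
    applies fates and opens units.
    """
    cand_ids = sorted(int(c) for c in band_cells)
    cand_ids = [c for c in cand_ids if ep.alive[ep.row(c)] and ep.fate[ep.row(c)] == int(Fate.PRECURSOR)]
    if not cand_ids:
        return []
    rows = ep.rows_of(cand_ids)
    pos = ep.pos[rows]
    ids = np.asarray(cand_ids, dtype=np.int64)

    excl = exclusion_to_world(fp.exclusion_radius, ep)
    margin = distance_to_world(fp.min_distance_from_edge, ep)
    edge_ok = ep.domain.edge_distance(pos) >= margin - 1e-9

    founders = [int(f) for f in existing_founders]
    if founders:
        fpos = ep.pos[ep.rows_of(founders)]
        mind = cKDTree(fpos).query(pos)[0]
    else:
        mind = np.full(len(ids), np.inf)

    selected: list[int] = []
    have_any = bool(founders)
    taken = np.zeros(len(ids), dtype=bool)
    while True:
        elig = edge_ok & ~taken & (mind >= excl - 1e-9)
        if not np.any(elig):
            break
        idx = np.flatnonzero(elig)
        if not have_any:
            # seed nearest the right (posterior) edge; ties by lowest id
            order = np.lexsort((ids[idx], -pos[idx, 0]))
            pick = idx[order[0]]
            have_any = True
        else:
            order = np.lexsort((ids[idx], mind[idx]))
            pick = idx[order[0]]
        taken[pick] = True
        selected.append(int(ids[pick]))
        d_new = np.hypot(pos[:, 0] - pos[pick, 0], pos[:, 1] - pos[pick, 1])
        mind = np.minimum(mind, d_new)
    return selected


# ---------------------------------------------------------------------------
# photoreceptor waves


def _wave_fate(wave_kind: int) -> Fate:
    return WAVE_FATES[wave_kind - 1]


def recruit_wave(
    unit: EyeUnit,
    wp: WaveParams,
    wave_kind: int,
    ep: Epithelium,
    rng: np.random.Generator | None = None,
    claimed: set[int] | None = None,
    furrow_x: float | None = None,
) -> list[int]:
    """Recruit one wave for one unit: the ``selection_count`` nearest
    unclaimed precursors within ``max_distance_from_r8`` of the founder
    (ties by lowest id).  Fewer are recruited when the pool is smaller.

    ``claimed`` lets a same-cycle cohort mark contested cells;
    ``furrow_x`` restricts candidates to the furrow's wake (x >= furrow_x).
    """
    if wave_kind not in (1, 2, 3):
        raise ParameterError(f"wave_kind must be 1, 2 or 3, got {wave_kind}")
    if unit.members[wave_kind]:
        raise ValueError(f"wave {wave_kind} already run for unit {unit.unit_id}")
    if wp.selection_count == 0:
        return []
    frow = ep.row(unit.founder_id)
    fpos = ep.pos[frow]
    maxd = distance_to_world(wp.max_distance_from_r8, ep)

    tree, trows = ep.tree()
    cand = tree.query_ball_point(fpos, maxd)
    rows = trows[np.asarray(cand, dtype=np.int64)] if cand else np.zeros(0, dtype=np.int64)
    mask = ep.fate[rows] == int(Fate.PRECURSOR)
    if furrow_x is not None:
        mask &= ep.pos[rows, 0] >= furrow_x
    rows = rows[mask]
    if claimed:
        rows = rows[[int(ep.ids[r]) not in claimed for r in rows]] if len(rows) else rows
    if len(rows) == 0:
        return []
    d = np.hypot(ep.pos[rows, 0] - fpos[0], ep.pos[rows, 1] - fpos[1])
    order = np.lexsort((ep.ids[rows], d))
    chosen = rows[order[: int(wp.selection_count)]]
    out = []
    for r in chosen:
        cid = int(ep.ids[r])
        ep.specify(cid, _wave_fate(wave_kind), wp.target_radius, unit.unit_id)
        unit.members[wave_kind].append(cid)
        out.append(cid)
    return out


def recruit_wave_cohort(
    units: list[EyeUnit],
    wp: WaveParams,
    wave_kind: int,
    ep: Epithelium,
    rng: np.random.Generator | None = None,
    furrow_x: float | None = None,
) -> dict[int, list[int]]:
    """Run one wave for several units in the same cycle.

    Cells in range of more than one firing founder are contested and go to the
    nearest founder (ties by lower unit id); each unit then takes its nearest
    ``selection_count`` from the cells assigned to it.
    """
    units = sorted(units, key=lambda u: u.unit_id)
    result: dict[int, list[int]] = {}
    if len(units) <= 1:
        for u in units:
            result[u.unit_id] = recruit_wave(u, wp, wave_kind, ep, rng, furrow_x=furrow_x)
        return result
    fpos = ep.pos[ep.rows_of([u.founder_id for u in units])]
    claimed: set[int] = set()
    # assign every in-range precursor to its nearest firing founder
    maxd = distance_to_world(wp.max_distance_from_r8, ep)
    tree, trows = ep.tree()
    assigned: dict[int, set[int]] = {u.unit_id: set() for u in units}
    seen: set[int] = set()
    for k, u in enumerate(units):
        for i in tree.query_ball_point(fpos[k], maxd):
            r = trows[i]
            cid = int(ep.ids[r])
            if cid in seen or ep.fate[r] != int(Fate.PRECURSOR):
                continue
            if furrow_x is not None and ep.pos[r, 0] < furrow_x:
                continue
            seen.add(cid)
            # nearest firing founder; ties resolve to the lowest unit id
            dall = np.hypot(fpos[:, 0] - ep.pos[r, 0], fpos[:, 1] - ep.pos[r, 1])
            j = int(np.flatnonzero(dall <= dall.min() + 1e-12)[0])
            assigned[units[j].unit_id].add(cid)
    for u in units:
        pool = assigned[u.unit_id] - claimed
        got = recruit_wave(
            u, wp, wave_kind, ep, rng,
            claimed=(seen - pool) | claimed,
            furrow_x=furrow_x,
        )
        claimed.update(got)
        result[u.unit_id] = got
    return result


# ---------------------------------------------------------------------------
# border cells


def _contact_precursor_neighbors(
    ep: Epithelium, frontier_ids, exclude: set[int], slack: float
) -> set[int]:
    """Precursor cells in contact with any frontier cell, minus ``exclude``."""
    out: set[int] = set()
    tree, trows = ep.tree()
    rmax = float(ep.radius[trows].max()) if len(trows) else 0.0
    for fid in frontier_ids:
        frow = ep.row(fid)
        for i in tree.query_ball_point(ep.pos[frow], ep.radius[frow] + rmax + slack):
            r = trows[i]
            cid = int(ep.ids[r])
            if cid in exclude or ep.fate[r] != int(Fate.PRECURSOR):
                continue
            d = float(np.hypot(*(ep.pos[r] - ep.pos[frow])))
            if d <= ep.radius[frow] + ep.radius[r] + slack:
                out.add(cid)
    return out


def recruit_border(
    unit: EyeUnit,
    bp: BorderParams,
    ep: Epithelium,
    claimed: set[int] | None = None,
) -> list[int]:
    """Recruit ``border_radius`` concentric layers of border cells.

    Layer 1 is the precursor contact ring of the unit's specified cells;
    layer k the precursor contact ring of layer k-1.
    """
    slack = 0.2 * ep.avg_cell_size
    exclude = set(unit.all_ids) | (claimed or set())
    frontier = list(unit.specified_ids)
    out: list[int] = []
    for _layer in range(int(bp.border_radius)):
        layer = _contact_precursor_neighbors(ep, frontier, exclude, slack)
        if not layer:
            break
        layer_ids = sorted(layer)
        for cid in layer_ids:
            ep.specify(cid, Fate.BORDER, bp.target_radius, unit.unit_id)
            unit.border_ids.append(cid)
        exclude.update(layer_ids)
        out.extend(layer_ids)
        frontier = layer_ids
    return out


def recruit_border_cohort(
    units: list[EyeUnit], bp: BorderParams, ep: Epithelium
) -> dict[int, list[int]]:
    """Border recruitment for several units in one cycle, layer by layer;
    a precursor adjacent to two units joins the nearer founder's unit
    (ties by lower unit id)."""
    units = sorted(units, key=lambda u: u.unit_id)
    result: dict[int, list[int]] = {u.unit_id: [] for u in units}
    if len(units) <= 1:
        for u in units:
            result[u.unit_id] = recruit_border(u, bp, ep)
        return result
    slack = 0.2 * ep.avg_cell_size
    fpos = {u.unit_id: ep.pos[ep.row(u.founder_id)].copy() for u in units}
    claimed: set[int] = set()
    frontiers = {u.unit_id: list(u.specified_ids) for u in units}
    for _layer in range(int(bp.border_radius)):
        want: dict[int, list[int]] = {}
        for u in units:
            exclude = set(u.all_ids) | claimed
            for cid in _contact_precursor_neighbors(ep, frontiers[u.unit_id], exclude, slack):
                want.setdefault(cid, []).append(u.unit_id)
        if not want:
            break
        new_frontiers = {u.unit_id: [] for u in units}
        byid = {u.unit_id: u for u in units}
        for cid in sorted(want):
            owners = want[cid]
            p = ep.pos[ep.row(cid)]
            owners.sort(key=lambda uid: (float(np.hypot(*(fpos[uid] - p))), uid))
            uid = owners[0]
            ep.specify(cid, Fate.BORDER, bp.target_radius, uid)
            byid[uid].border_ids.append(cid)
            result[uid].append(cid)
            new_frontiers[uid].append(cid)
            claimed.add(cid)
        frontiers = new_frontiers
    return result


# ---------------------------------------------------------------------------
# apoptosis


def apoptosis_step(
    ep: Epithelium,
    fs,
    dp: DeathParams,
    rng: np.random.Generator,
    restrict_ids=None,
) -> list[int]:
    """Remove precursors behind the death threshold, each independently with
    probability ``death_chance/100`` this cycle.  Specified cells never die.

    ``restrict_ids`` limits the lottery to a subset (used for one-shot
    band-delivered death)."""
    dp.validate()
    if dp.death_chance == 0.0:
        return []
    rows = ep.alive_rows()
    mask = (ep.fate[rows] == int(Fate.PRECURSOR)) & (
        ep.pos[rows, 0] >= fs.x + dp.distance_from_furrow
    )
    rows = rows[mask]
    if restrict_ids is not None:
        allowed = set(int(i) for i in restrict_ids)
        rows = rows[[int(ep.ids[r]) in allowed for r in rows]] if len(rows) else rows
    if len(rows) == 0:
        return []
    die = rng.random(len(rows)) < dp.death_chance / 100.0
    removed = [int(ep.ids[r]) for r in rows[die]]
    if removed:
        ep.kill(removed)
    return removed
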