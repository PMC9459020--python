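"""Layout metrics: unit censuses, founder spacing, radial wave profiles,
and the expansion-vs-fusion signature.

The regularity statistic is the coefficient of variation of nearest-neighbor
founder distances: 0 for a perfect lattice, ~0.5 for Poisson seeding — the
simplest number separating a roughly hexagonal ommatidial array from random
placement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .epithelium import Epithelium, Fate, WAVE_FATES
from .furrow import SimulationState
from .specification import EyeUnit


@dataclass(frozen=True)
class UnitCensus:
    """Per-unit composition and geometry."""

    unit_id: int
    counts: dict[str, int]  # fate name -> count (R8 included)
    founder_pos: tuple[float, float]
    centroid: tuple[float, float]
    unit_radius: float  # max member distance to founder

    @property
    def wave_total(self) -> int:
        return sum(self.counts.get(f.name, 0) for f in WAVE_FATES)


def _units_of(state) -> dict[int, EyeUnit]:
    if isinstance(state, SimulationState):
        return state.units
    return units_from_epithelium(state)


def _ep_of(state) -> Epithelium:
    return state.ep if isinstance(state, SimulationState) else state


def units_from_epithelium(ep: Epithelium) -> dict[int, EyeUnit]:
    """Reconstruct unit membership from the cell table's unit_id/fate columns
    (wave order is recoverable from the fates)."""
    units: dict[int, EyeUnit] = {}
    for row in ep.alive_rows():
        uid = int(ep.unit_id[row])
        if uid < 0:
            continue
        fate = Fate(int(ep.fate[row]))
        cid = int(ep.ids[row])
        if uid not in units:
            units[uid] = EyeUnit(unit_id=uid, founder_id=-1)
        u = units[uid]
        if fate == Fate.R8:
            u.founder_id = cid
        elif fate in WAVE_FATES:
            u.members[WAVE_FATES.index(fate) + 1].append(cid)
        elif fate == Fate.BORDER:
            u.border_ids.append(cid)
    return {k: u for k, u in sorted(units.items()) if u.founder_id >= 0}


def census(state) -> list[UnitCensus]:
    """One record per eye unit; totals reconcile with the event log
    (initial count + divisions - removals = living cells)."""
    ep = _ep_of(state)
    units = _units_of(state)
    out = []
    for uid in sorted(units):
        u = units[uid]
        alive_members = [c for c in u.all_ids if ep.alive[ep.row(c)]]
        counts: dict[str, int] = {}
        for cid in alive_members:
            name = Fate(int(ep.fate[ep.row(cid)])).name
            counts[name] = counts.get(name, 0) + 1
        fpos = ep.pos[ep.row(u.founder_id)]
        pos = ep.pos[ep.rows_of(alive_members)]
        centroid = pos.mean(axis=0) if len(pos) else fpos
        radius = float(np.hypot(pos[:, 0] - fpos[0], pos[:, 1] - fpos[1]).max()) if len(pos) else 0.0
        out.append(
            UnitCensus(
                unit_id=uid,
                counts=counts,
                founder_pos=(float(fpos[0]), float(fpos[1])),
                centroid=(float(centroid[0]), float(centroid[1])),
                unit_radius=radius,
            )
        )
    return out


def unit_count(state) -> int:
    """Number of eye units (= number of founders)."""
    return len(_units_of(state))


def founder_positions(state) -> np.ndarray:
    ep = _ep_of(state)
    rows = ep.alive_rows()
    return ep.pos[rows[ep.fate[rows] == int(Fate.R8)]]


def founder_spacing(state) -> dict:
    """Pairwise and nearest-neighbor founder distance statistics, world units.

    With fewer than two founders every statistic is None (defined empty
    result); with exactly two, the nearest-neighbor cv is 0 by convention.
    """
    pos = founder_positions(state)
    n = len(pos)
    if n < 2:
        return {"n": n, "min": None, "mean": None, "nn_mean": None, "nn_cv": None}
    diffs = pos[:, None, :] - pos[None, :, :]
    d = np.hypot(diffs[..., 0], diffs[..., 1])
    iu = np.triu_indices(n, k=1)
    pair = d[iu]
    nn = np.where(np.eye(n, dtype=bool), np.inf, d).min(axis=1)
    nn_cv = float(nn.std() / nn.mean()) if n > 2 else 0.0
    return {
        "n": n,
        "min": float(pair.min()),
        "mean": float(pair.mean()),
        "nn_mean": float(nn.mean()),
        "nn_cv": nn_cv,
    }


def wave_radial_profile(state, unit_id: int) -> dict[int, float]:
    """Mean member distance to the founder, per recruitment wave.

    Entries are absent for unpopulated waves.  For expansion-built single
    eyes the profile increases with wave number (concentric recruitment)."""
    ep = _ep_of(state)
    units = _units_of(state)
    if unit_id not in units:
        raise KeyError(f"unknown unit {unit_id}")
    u = units[unit_id]
    fpos = ep.pos[ep.row(u.founder_id)]
    out: dict[int, float] = {}
    for k in (1, 2, 3):
        members = [c for c in u.members[k] if ep.alive[ep.row(c)]]
        if not members:
            continue
        pos = ep.pos[ep.rows_of(members)]
        out[k] = float(np.hypot(pos[:, 0] - fpos[0], pos[:, 1] - fpos[1]).mean())
    return out


def wave_label_assortativity(
    state, contact_slack: float | None = None, include_founders: bool = True
) -> float:
    """Spatial autocorrelation of photoreceptor identity over contact pairs.

    Pearson correlation of recruitment-order labels (founder=0, waves 1..3)
    across all ordered contact pairs of photoreceptors.  Concentric
    (expansion-built) retinas score strongly positive; an interleaved fusion
    mosaic of receptor types scores near zero.  ``include_founders=False``
    restricts the labels to the three waves.  Returns 0.0 when there are no
    pairs or no label variance.
    """
    ep = _ep_of(state)
    if contact_slack is None:
        contact_slack = 0.2 * ep.avg_cell_size
    fates = ((Fate.R8,) if include_founders else ()) + WAVE_FATES
    rows = ep.alive_rows()
    wmask = np.isin(ep.fate[rows], [int(f) for f in fates])
    rows = rows[wmask]
    if len(rows) < 2:
        return 0.0
    pos = ep.pos[rows]
    rad = ep.radius[rows]
    labels = ep.fate[rows].astype(float) - float(Fate.R8)  # founder=0, waves 1..3
    tree = cKDTree(pos)
    pairs = tree.query_pairs(2.0 * rad.max() + contact_slack, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.hypot(*(pos[i] - pos[j]).T)
    keep = d <= rad[i] + rad[j] + contact_slack
    i, j = i[keep], j[keep]
    if len(i) == 0:
        return 0.0
    a = np.concatenate([labels[i], labels[j]])
    b = np.concatenate([labels[j], labels[i]])
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def census_conservation(state) -> dict:
    """Bookkeeping identity: initial count + divisions - removals = alive."""
    ep = _ep_of(state)
    expected = ep.initial_count + len(ep.divisions) - len(ep.deaths)
    return {
        "initial": ep.initial_count,
        "divisions": len(ep.divisions),
        "deaths": len(ep.deaths),
        "alive": ep.n_alive,
        "balanced": expected == ep.n_alive,
    }


def metrics_frame(state) -> pd.DataFrame:
    """Tidy per-unit metrics table (one row per eye unit)."""
    recs = []
    for c in census(state):
        rec = {
            "unit_id": c.unit_id,
            "founder_x": c.founder_pos[0],
            "founder_y": c.founder_pos[1],
            "centroid_x": c.centroid[0],
            "centroid_y": c.centroid[1],
            "unit_radius": c.unit_radius,
            "wave_total": c.wave_total,
        }
        for f in Fate:
            rec[f"n_{f.name.lower()}"] = c.counts.get(f.name, 0)
        recs.append(rec)
    cols = [
        "unit_id", "founder_x", "founder_y", "centroid_x", "centroid_y",
        "unit_radius", "wave_total",
    ] + [f"n_{f.name.lower()}" for f in Fate]
    return pd.DataFrame(recs, columns=cols)


def summary(state) -> dict:
    """Run-level summary used by the CLI's summary JSON."""
    sp = founder_spacing(state)
    return {
        "n_units": unit_count(state),
        "n_cells": _ep_of(state).n_alive,
        "founder_spacing": sp,
        "wave_label_assortativity": wave_label_assortativity(state),
        "conservation": census_conservation(state),
    }


def export_metrics(state, csv_path, json_path=None) -> None:
    metrics_frame(state).to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(summary(state), fh, indent=2)
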