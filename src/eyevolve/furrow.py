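"""The morphogenetic furrow sweep and its distance-gated event schedule.

A virtual vertical line starts at the right (posterior) domain edge and moves
left by ``furrow_velocity`` world units per cycle.  Each event kind acts on
the vertical slice of tissue its offset trails behind the furrow; within a
cycle events run in ascending offset order, so founder selection (offset 0)
always precedes the photoreceptor waves, border recruitment and death.
Recruitment events are delivered to each cell at most once; death is a
per-cycle hazard behind its threshold.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .epithelium import Epithelium, Fate, ParameterError, grow_step, relax
from .params import SimulationParams
from .specification import (
    EyeUnit,
    apoptosis_step,
    recruit_border_cohort,
    recruit_wave_cohort,
    select_founders,
)


class StateError(RuntimeError):
    """An operation was applied to a state that cannot accept it."""


class EventKind(enum.IntEnum):
    FOUNDER = 0
    WAVE1 = 1
    WAVE2 = 2
    WAVE3 = 3
    BORDER = 4
    DEATH = 5


@dataclass(frozen=True)
class FurrowState:
    """Furrow position in world units; x is non-increasing over cycles."""

    x: float
    velocity: float
    cycle: int = 0
    finished: bool = False
    finish_x: float = float("-inf")  # xmin - trailing-most event offset


def advance_furrow(fs: FurrowState) -> FurrowState:
    """Move the furrow one cycle leftward; flags ``finished`` once the
    trailing-most event offset has cleared the left domain edge."""
    if fs.finished:
        raise StateError("cannot advance a finished furrow")
    x = fs.x - fs.velocity
    return replace(fs, x=x, cycle=fs.cycle + 1, finished=x < fs.finish_x)


@dataclass(frozen=True)
class EventSpec:
    """One furrow event: what fires, how far behind the furrow, with what."""

    kind: EventKind
    distance_from_furrow: float  # world units, >= 0
    params: object


def build_schedule(params: SimulationParams) -> list[EventSpec]:
    """Event schedule from the parameter set, ascending by offset
    (ties resolved by the developmental order founder < waves < border < death)."""
    specs = [
        EventSpec(EventKind.FOUNDER, params.founder.distance_from_furrow, params.founder),
        EventSpec(EventKind.WAVE1, params.waves[0].distance_from_furrow, params.waves[0]),
        EventSpec(EventKind.WAVE2, params.waves[1].distance_from_furrow, params.waves[1]),
        EventSpec(EventKind.WAVE3, params.waves[2].distance_from_furrow, params.waves[2]),
        EventSpec(EventKind.BORDER, params.border.distance_from_furrow, params.border),
        EventSpec(EventKind.DEATH, params.death.distance_from_furrow, params.death),
    ]
    return sorted(specs, key=lambda s: (s.distance_from_furrow, int(s.kind)))


@dataclass
class SimulationState:
    """Everything a run carries: tissue, furrow, units, schedule, logs, RNG."""

    ep: Epithelium
    furrow: FurrowState
    params: SimulationParams
    schedule: list[EventSpec]
    units: dict[int, EyeUnit] = field(default_factory=dict)
    event_log: list[dict] = field(default_factory=list)
    rng_streams: dict[str, np.random.Generator] = field(default_factory=dict)
    received: dict[EventKind, set[int]] = field(
        default_factory=lambda: {k: set() for k in EventKind}
    )
    _next_unit_id: int = 0

    def log(self, kind: str, cell_ids, unit_id=None) -> None:
        self.event_log.append(
            {
                "cycle": self.furrow.cycle,
                "kind": kind,
                "cell_ids": [int(c) for c in cell_ids],
                "unit_id": unit_id,
            }
        )

    def new_unit(self, founder_id: int) -> EyeUnit:
        u = EyeUnit(unit_id=self._next_unit_id, founder_id=founder_id)
        self._next_unit_id += 1
        self.units[u.unit_id] = u
        return u

    def export_event_log(self, path) -> None:
        """JSON-lines, one record per mutation."""
        with open(path, "w") as fh:
            for rec in self.event_log:
                fh.write(json.dumps(rec) + "\n")


def cells_in_band(ep: Epithelium, fs: FurrowState, spec: EventSpec, received=None) -> list[int]:
    """Living cells this event sweeps this cycle: center x at or behind the
    event's offset line (x >= furrow.x + offset) that have not yet received
    this event kind.

    On a static tissue this is exactly the velocity-wide band
    [furrow.x + offset, furrow.x + offset + velocity) the furrow moved across
    this cycle; tracking delivery instead of the band's upper edge keeps the
    sweep exactly-once *and* robust when the growing tissue drifts faster
    than the furrow (a strict band can then miss cells forever).  Cells ahead
    of the furrow are never returned."""
    lo = fs.x + spec.distance_from_furrow
    rows = ep.alive_rows()
    mask = ep.pos[rows, 0] >= lo
    out = [int(i) for i in np.sort(ep.ids[rows[mask]])]
    if received is not None:
        got = received[spec.kind]
        out = [c for c in out if c not in got]
    return out


def _founder_ids(state: SimulationState) -> list[int]:
    return [u.founder_id for u in state.units.values()]


def init_state(
    params: SimulationParams, ep: Epithelium, seed: int | None = None
) -> SimulationState:
    """Build a fresh simulation state with per-event-kind RNG child streams."""
    params.validate()
    if ep.n_alive == 0:
        raise ParameterError("epithelium is empty")
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    ss = np.random.SeedSequence(seed)
    names = ("growth", "founder", "wave", "death")
    streams = {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}
    schedule = build_schedule(params)
    max_off = max(s.distance_from_furrow for s in schedule)
    fs = FurrowState(
        x=ep.domain.xmax,
        velocity=params.furrow_velocity,
        finish_x=ep.domain.xmin - max_off,
    )
    return SimulationState(ep=ep, furrow=fs, params=params, schedule=schedule,
                           rng_streams=streams)


def run_cycle(state: SimulationState, relax_iters: int = 4) -> SimulationState:
    """One simulation cycle: grow (and divide), relax, advance the furrow,
    then fire every scheduled event on its band, logging each mutation.
    Deterministic given (state, rng streams)."""
    if state.furrow.finished:
        raise StateError("cannot run a cycle on a finished furrow")
    ep, p = state.ep, state.params
    _, divided = grow_step(ep, p.cell_growth_rate, p.cell_max_size, state.rng_streams["growth"])
    for parent, child in ep.divisions[len(ep.divisions) - len(divided):]:
        state.log("DIVIDE", [parent, child])
    if relax_iters > 0 and ep.n_alive > 0:
        relax(ep, max_iters=relax_iters, overlap_tolerance=0.05 * ep.avg_cell_size,
              clamp=False, refresh_every=2)
    state.furrow = advance_furrow(state.furrow)
    fs = state.furrow

    for spec in state.schedule:
        if spec.kind == EventKind.FOUNDER:
            band = cells_in_band(ep, fs, spec, state.received)
            state.received[EventKind.FOUNDER].update(band)
            if not band:
                continue
            new = select_founders(band, _founder_ids(state), spec.params, ep,
                                  state.rng_streams["founder"])
            for cid in new:
                u = state.new_unit(cid)
                ep.specify(cid, Fate.R8, spec.params.target_radius, u.unit_id)
                state.log("FOUNDER", [cid], u.unit_id)
        elif spec.kind in (EventKind.WAVE1, EventKind.WAVE2, EventKind.WAVE3):
            wave_k = int(spec.kind)  # 1..3
            band = cells_in_band(ep, fs, spec, state.received)
            state.received[spec.kind].update(band)
            firing = [
                state.units[int(ep.unit_id[ep.row(c)])]
                for c in band
                if ep.fate[ep.row(c)] == int(Fate.R8)
            ]
            if not firing:
                continue
            got = recruit_wave_cohort(firing, spec.params, wave_k, ep,
                                      state.rng_streams["wave"], furrow_x=fs.x)
            for uid in sorted(got):
                if got[uid]:
                    state.log(spec.kind.name, got[uid], uid)
        elif spec.kind == EventKind.BORDER:
            band = cells_in_band(ep, fs, spec, state.received)
            state.received[EventKind.BORDER].update(band)
            firing = [
                state.units[int(ep.unit_id[ep.row(c)])]
                for c in band
                if ep.fate[ep.row(c)] == int(Fate.R8)
            ]
            if not firing:
                continue
            got = recruit_border_cohort(firing, spec.params, ep)
            for uid in sorted(got):
                if got[uid]:
                    state.log("BORDER", got[uid], uid)
        elif spec.kind == EventKind.DEATH:
            dp = spec.params
            if dp.one_shot:
                band = cells_in_band(ep, fs, spec, state.received)
                state.received[EventKind.DEATH].update(band)
                removed = apoptosis_step(ep, fs, dp, state.rng_streams["death"],
                                         restrict_ids=band)
            else:
                removed = apoptosis_step(ep, fs, dp, state.rng_streams["death"])
            if removed:
                state.log("DEATH", removed)
    return state


def run_simulation(
    params: SimulationParams,
    ep: Epithelium,
    seed: int | None = None,
    stop_after_furrow: bool = False,
    relax_iters: int = 4,
    max_cycles: int = 100_000,
    settle_max_iters: int = 4000,
    on_cycle=None,
) -> SimulationState:
    """Run the furrow across the epithelium, then complete development.

    After the furrow finishes, cycles continue until every specified cell has
    reached its target radius.  During completion the death hazard keeps
    acting (its threshold region has swept the whole tissue by then), so the
    leftover undifferentiated cells are pruned away, as in the finished eyes.
    Finally the tissue settles: a long relaxation lets the fully grown units
    expand to their packed equilibrium.  ``stop_after_furrow`` skips
    completion and settling.  ``on_cycle(state)`` is called after each cycle
    (snapshots, progress)."""
    state = init_state(params, ep, seed)
    while not state.furrow.finished:
        run_cycle(state, relax_iters=relax_iters)
        if on_cycle is not None:
            on_cycle(state)
        if state.furrow.cycle >= max_cycles:
            break
    if stop_after_furrow:
        return state
    # post-furrow completion: specified cells finish growing in place while
    # the remaining precursors keep dividing and dying off
    dp = params.death
    everywhere = replace(state.furrow, x=float("-inf"))
    pruning = dp.death_chance > 0 and not dp.one_shot
    if params.cell_growth_rate > 0:
        for extra in range(max_cycles):
            rows = state.ep.alive_rows()
            spec_rows = rows[state.ep.fate[rows] != int(Fate.PRECURSOR)]
            growing = len(spec_rows) > 0 and not np.all(
                state.ep.radius[spec_rows] >= state.ep.target_radius[spec_rows] - 1e-9
            )
            n_prec = len(rows) - len(spec_rows)
            # run until growth completes and (with a nonzero hazard) the
            # leftover undifferentiated cells have been pruned away; a tissue
            # whose every cell died (no unit ever seeded) simply ends
            if len(rows) == 0:
                break
            if not growing and not (pruning and n_prec > 0 and extra < 1000):
                break
            _, divided = grow_step(state.ep, params.cell_growth_rate, params.cell_max_size,
                                   state.rng_streams["growth"])
            for parent, child in state.ep.divisions[len(state.ep.divisions) - len(divided):]:
                state.log("DIVIDE", [parent, child])
            if not dp.one_shot and dp.death_chance > 0:
                removed = apoptosis_step(state.ep, everywhere, dp, state.rng_streams["death"])
                if removed:
                    state.log("DEATH", removed)
            if relax_iters > 0 and state.ep.n_alive > 0:
                relax(state.ep, max_iters=relax_iters,
                      overlap_tolerance=0.05 * state.ep.avg_cell_size, clamp=False)
            if on_cycle is not None:
                on_cycle(state)
    if settle_max_iters > 0 and state.ep.n_alive > 0:
        # settling: the growth-compressed transient expands toward the packed
        # equilibrium.  A moderately larger step (still below the per-pair
        # overshoot limit) and a mildly stale pair list speed up the slow,
        # boundary-limited expansion mode without scrambling unit geometry.
        relax(state.ep, max_iters=settle_max_iters,
              overlap_tolerance=0.05 * state.ep.avg_cell_size, clamp=False,
              k_rep=0.8, refresh_every=5)
    return state
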