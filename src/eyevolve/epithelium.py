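"""The precursor cell sheet: generation, relaxation, growth/division, persistence.

The epithelium is an off-lattice collection of circular cells in an
axis-aligned rectangular domain.  Cells are stored in struct-of-arrays form
(positions, radii, fates, ...) so that relaxation and growth are vectorised;
:class:`Cell` objects are immutable snapshots built on demand.

Rows are append-only and ordered by id; apoptotic cells keep their row with
``alive=False``.  This makes every vectorised pass deterministic for a given
seed and keeps id -> row lookup O(1).
"""

from __future__ import annotations

import csv
import enum
import io
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree


class ParameterError(ValueError):
    """An input parameter is out of range; the message names the field."""


class FormatError(ValueError):
    """A persisted cell table could not be parsed."""


class Fate(enum.IntEnum):
    """Cell identity.  PRECURSOR may transition once to a specified fate;
    specified fates are terminal."""

    PRECURSOR = 0
    R8 = 1
    PR_WAVE1 = 2
    PR_WAVE2 = 3
    PR_WAVE3 = 4
    BORDER = 5


#: the three sequential photoreceptor recruitment fates, in temporal order
WAVE_FATES = (Fate.PR_WAVE1, Fate.PR_WAVE2, Fate.PR_WAVE3)
SPECIFIED_FATES = (Fate.R8,) + WAVE_FATES + (Fate.BORDER,)


@dataclass(frozen=True)
class Domain:
    """Axis-aligned rectangle holding the tissue, in world units."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    def contains(self, xy) -> bool:
        x, y = xy
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax

    def edge_distance(self, pos: np.ndarray) -> np.ndarray:
        """Distance from each position (n,2) to the nearest domain edge."""
        pos = np.atleast_2d(pos)
        return np.minimum.reduce(
            [
                pos[:, 0] - self.xmin,
                self.xmax - pos[:, 0],
                pos[:, 1] - self.ymin,
                self.ymax - pos[:, 1],
            ]
        )


@dataclass(frozen=True)
class Cell:
    """Immutable snapshot of one cell."""

    id: int
    pos: tuple[float, float]
    radius: float
    fate: Fate
    target_radius: float
    unit_id: int | None
    alive: bool


class Epithelium:
    """Growable cell collection with a spatial index.

    Mutation goes through :meth:`add_cell`, :meth:`kill`, and the array
    setters used by the relaxation/growth routines; any mutation must call
    :meth:`touch` to invalidate cached spatial indices.
    """

    _CAP0 = 256

    def __init__(self, domain: Domain, avg_cell_size: float):
        self.domain = domain
        self.avg_cell_size = float(avg_cell_size)
        cap = self._CAP0
        self.ids = np.zeros(cap, dtype=np.int64)
        self.pos = np.zeros((cap, 2), dtype=np.float64)
        self.radius = np.zeros(cap, dtype=np.float64)
        self.fate = np.zeros(cap, dtype=np.int8)
        self.target_radius = np.zeros(cap, dtype=np.float64)
        self.unit_id = np.full(cap, -1, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=bool)
        self.n = 0  # rows in use
        self._next_id = 0
        self._row_of: dict[int, int] = {}
        self._version = 0
        self._tree_cache: tuple[int, cKDTree, np.ndarray] | None = None
        self._delaunay_cache: tuple[int, Delaunay, np.ndarray] | None = None
        # conservation bookkeeping
        self.initial_count = 0
        self.divisions: list[tuple[int, int]] = []  # (parent id, daughter id)
        self.deaths: list[int] = []
        self.last_relax: dict | None = None

    # -- storage ----------------------------------------------------------

    def _grow_capacity(self, need: int) -> None:
        cap = len(self.ids)
        if need <= cap:
            return
        new = max(need, cap * 2)
        for name in ("ids", "radius", "fate", "target_radius", "unit_id", "alive"):
            arr = getattr(self, name)
            out = np.zeros(new, dtype=arr.dtype)
            if name == "unit_id":
                out[:] = -1
            out[: self.n] = arr[: self.n]
            setattr(self, name, out)
        pos = np.zeros((new, 2), dtype=np.float64)
        pos[: self.n] = self.pos[: self.n]
        self.pos = pos

    def touch(self) -> None:
        self._version += 1

    def add_cell(
        self,
        pos,
        radius: float,
        fate: Fate = Fate.PRECURSOR,
        target_radius: float | None = None,
        unit_id: int | None = None,
        cell_id: int | None = None,
        alive: bool = True,
    ) -> int:
        if radius <= 0:
            raise ParameterError(f"radius must be positive, got {radius}")
        cid = self._next_id if cell_id is None else int(cell_id)
        self._next_id = max(self._next_id, cid + 1)
        row = self.n
        self._grow_capacity(row + 1)
        self.ids[row] = cid
        self.pos[row] = pos
        self.radius[row] = radius
        self.fate[row] = int(fate)
        self.target_radius[row] = radius if target_radius is None else target_radius
        self.unit_id[row] = -1 if unit_id is None else unit_id
        self.alive[row] = alive
        self.n = row + 1
        self._row_of[cid] = row
        self.touch()
        return cid

    def kill(self, cell_ids) -> None:
        for cid in cell_ids:
            row = self._row_of[cid]
            if self.alive[row]:
                self.alive[row] = False
                self.deaths.append(int(cid))
        self.touch()

    # -- views ------------------------------------------------------------

    def __len__(self) -> int:
        return int(np.count_nonzero(self.alive[: self.n]))

    @property
    def n_alive(self) -> int:
        return len(self)

    def alive_rows(self) -> np.ndarray:
        return np.flatnonzero(self.alive[: self.n])

    def alive_ids(self) -> np.ndarray:
        return self.ids[self.alive_rows()]

    def row(self, cell_id: int) -> int:
        try:
            return self._row_of[int(cell_id)]
        except KeyError:
            raise KeyError(f"unknown cell id {cell_id}") from None

    def rows_of(self, cell_ids) -> np.ndarray:
        return np.array([self.row(c) for c in cell_ids], dtype=np.int64)

    def cell(self, cell_id: int) -> Cell:
        r = self.row(cell_id)
        uid = int(self.unit_id[r])
        return Cell(
            id=int(self.ids[r]),
            pos=(float(self.pos[r, 0]), float(self.pos[r, 1])),
            radius=float(self.radius[r]),
            fate=Fate(int(self.fate[r])),
            target_radius=float(self.target_radius[r]),
            unit_id=None if uid < 0 else uid,
            alive=bool(self.alive[r]),
        )

    @property
    def cells(self) -> dict[int, Cell]:
        """Snapshot of all living cells keyed by id (copies; not a live view)."""
        return {int(self.ids[r]): self.cell(int(self.ids[r])) for r in self.alive_rows()}

    # -- spatial index -----------------------------------------------------

    def tree(self) -> tuple[cKDTree, np.ndarray]:
        """cKDTree over living cell centers plus the row indices it was built on."""
        if self._tree_cache is None or self._tree_cache[0] != self._version:
            rows = self.alive_rows()
            pts = self.pos[rows] if len(rows) else np.zeros((0, 2))
            self._tree_cache = (self._version, cKDTree(pts), rows)
        return self._tree_cache[1], self._tree_cache[2]

    def specify(self, cell_id: int, fate: Fate, target_radius: float, unit_id: int) -> None:
        """Differentiate a precursor.  Fate transitions are monotone: any
        attempt to respecify raises."""
        r = self.row(cell_id)
        if Fate(int(self.fate[r])) != Fate.PRECURSOR:
            raise ValueError(
                f"cell {cell_id} already specified as {Fate(int(self.fate[r])).name}"
            )
        if fate == Fate.PRECURSOR:
            raise ValueError("cannot specify a cell as PRECURSOR")
        self.fate[r] = int(fate)
        # a cell never shrinks toward a smaller specified target
        self.target_radius[r] = max(float(target_radius), float(self.radius[r]))
        self.unit_id[r] = unit_id
        self.touch()

    # -- neighbour queries -------------------------------------------------

    def neighbors(self, cell_id: int, mode="contact", contact_slack: float | None = None):
        """Neighbouring cell ids under one of three adjacency notions.

        ``"contact"``    center distance <= r_i + r_j + contact_slack
        ``"delaunay"``   Delaunay-graph neighbours of the living cells
        ``"radius:r"``   centers within distance r (also ``("radius", r)``)
        """
        row = self.row(cell_id)
        if not self.alive[row]:
            return []
        if contact_slack is None:
            contact_slack = 0.2 * self.avg_cell_size
        tree, rows = self.tree()
        if isinstance(mode, tuple) and mode[0] == "radius":
            mode = f"radius:{mode[1]}"
        if mode == "contact":
            rmax = float(self.radius[rows].max()) if len(rows) else 0.0
            cand = tree.query_ball_point(self.pos[row], self.radius[row] + rmax + contact_slack)
            out = []
            for i in cand:
                rr = rows[i]
                if rr == row:
                    continue
                d = math.hypot(*(self.pos[rr] - self.pos[row]))
                if d <= self.radius[row] + self.radius[rr] + contact_slack:
                    out.append(int(self.ids[rr]))
            return sorted(out)
        if mode == "delaunay":
            if len(rows) < 4:
                return []
            if self._delaunay_cache is None or self._delaunay_cache[0] != self._version:
                self._delaunay_cache = (self._version, Delaunay(self.pos[rows]), rows)
            tri, trows = self._delaunay_cache[1], self._delaunay_cache[2]
            local = int(np.flatnonzero(trows == row)[0])
            indptr, indices = tri.vertex_neighbor_vertices
            nbrs = indices[indptr[local] : indptr[local + 1]]
            return sorted(int(self.ids[trows[i]]) for i in nbrs)
        if isinstance(mode, str) and mode.startswith("radius:"):
            r = float(mode.split(":", 1)[1])
            if r <= 0:
                return []
            cand = tree.query_ball_point(self.pos[row], r)
            return sorted(int(self.ids[rows[i]]) for i in cand if rows[i] != row)
        raise ValueError(f"unknown neighbor mode {mode!r}")

    def max_overlap(self) -> float:
        """Largest pairwise overlap depth max(0, r_i + r_j - d) among living cells."""
        rows = self.alive_rows()
        if len(rows) < 2:
            return 0.0
        tree, trows = self.tree()
        rmax = float(self.radius[trows].max())
        pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
        if len(pairs) == 0:
            return 0.0
        a, b = trows[pairs[:, 0]], trows[pairs[:, 1]]
        d = np.hypot(*(self.pos[a] - self.pos[b]).T)
        return float(np.maximum(0.0, self.radius[a] + self.radius[b] - d).max())

    def copy(self) -> "Epithelium":
        out = Epithelium(self.domain, self.avg_cell_size)
        out._grow_capacity(self.n)
        for name in ("ids", "radius", "fate", "target_radius", "unit_id", "alive"):
            getattr(out, name)[: self.n] = getattr(self, name)[: self.n]
        out.pos[: self.n] = self.pos[: self.n]
        out.n = self.n
        out._next_id = self._next_id
        out._row_of = dict(self._row_of)
        out.initial_count = self.initial_count
        out.divisions = list(self.divisions)
        out.deaths = list(self.deaths)
        out.touch()
        return out


# ---------------------------------------------------------------------------
# generation


def generate_epithelium(
    min_cell_count: int,
    avg_cell_size: float,
    cell_size_variance: float,
    seed: int | None = 0,
    relax_max_iters: int = 400,
    overlap_tolerance: float | None = None,
) -> Epithelium:
    """Create and relax a precursor sheet of exactly ``min_cell_count`` cells.

    Radii are drawn Normal(avg, sd=cell_size_variance), truncated below at a
    small positive floor; cells are seeded on a jittered square grid sized to
    hold the population at the mean radius, then relaxed until the pairwise
    overlap invariant holds.  Identical (seed, parameters) give identical
    tissue.
    """
    if not isinstance(min_cell_count, (int, np.integer)) or min_cell_count < 1:
        raise ParameterError(f"min_cell_count must be a positive integer, got {min_cell_count}")
    if avg_cell_size <= 0:
        raise ParameterError(f"avg_cell_size must be positive, got {avg_cell_size}")
    if cell_size_variance < 0:
        raise ParameterError(f"cell_size_variance must be >= 0, got {cell_size_variance}")

    n = int(min_cell_count)
    rng = np.random.default_rng(seed)
    m = math.ceil(math.sqrt(n))
    spacing = 2.0 * avg_cell_size
    side = m * spacing
    domain = Domain(0.0, side, 0.0, side)
    ep = Epithelium(domain, avg_cell_size)

    gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()]) * spacing + spacing / 2.0
    centers = centers[:n].astype(np.float64)
    if n > 1:
        centers = centers + rng.uniform(-0.3, 0.3, size=centers.shape) * avg_cell_size
    else:
        centers = np.array([[side / 2.0, side / 2.0]])

    floor = 0.1 * avg_cell_size
    radii = rng.normal(avg_cell_size, cell_size_variance, size=n)
    radii = np.maximum(radii, floor)

    for i in range(n):
        ep.add_cell(centers[i], radii[i])
    ep.initial_count = n

    if overlap_tolerance is None:
        overlap_tolerance = 0.05 * avg_cell_size
    relax(ep, max_iters=relax_max_iters, overlap_tolerance=overlap_tolerance)
    return ep


# ---------------------------------------------------------------------------
# relaxation


def relax(
    ep: Epithelium,
    max_iters: int = 100,
    overlap_tolerance: float | None = None,
    k_rep: float = 0.5,
    k_att: float = 0.02,
    gap_threshold: float | None = None,
    clamp: bool = True,
    refresh_every: int = 1,
) -> Epithelium:
    """Iteratively resolve overlaps with linear pair springs.

    Overlapping pairs repel along their center line proportionally to overlap
    depth; near pairs with a gap above ``gap_threshold`` attract weakly, which
    keeps the sheet cohesive.  Iteration stops when the largest overlap depth
    is at most ``overlap_tolerance`` or after ``max_iters``.  Non-convergence
    is reported (in ``ep.last_relax``), never raised.

    With ``clamp`` (the default, used while packing the initial tissue) cell
    centers are clamped to the domain; simulation cycles relax unclamped, so
    the sheet can expand past its initial footprint as cells grow and divide
    — the domain then records the starting geometry the furrow sweeps.

    ``refresh_every`` rebuilds the neighbor-pair list only every that many
    iterations; with the small per-iteration displacements of a settling
    tissue, a slightly stale pair list changes nothing but the runtime.
    """
    if ep.n_alive == 0:
        raise ParameterError("cannot relax an empty epithelium")
    if overlap_tolerance is None:
        overlap_tolerance = 0.05 * ep.avg_cell_size
    if gap_threshold is None:
        gap_threshold = 0.5 * ep.avg_cell_size

    rows = ep.alive_rows()
    P = ep.pos[rows].copy()
    R = ep.radius[rows]
    dom = ep.domain
    inset = 1e-9 * max(dom.width, dom.height)
    report = {"iterations": 0, "displacements": [], "max_overlap": 0.0, "converged": True}

    if len(rows) == 1:
        ep.last_relax = report
        return ep

    att_range = 2.0 * gap_threshold
    npts = len(P)
    i = j = sumr = None
    for it in range(max_iters):
        if i is None or it % refresh_every == 0:
            tree = cKDTree(P)
            rmax = float(R.max())
            pairs = tree.query_pairs(2.0 * rmax + att_range, output_type="ndarray")
            if len(pairs) == 0:
                report["max_overlap"] = 0.0
                break
            i, j = pairs[:, 0], pairs[:, 1]
            sumr = R[i] + R[j]
            # keep only pairs near interaction range; the margin covers the
            # drift possible within one stale window
            d0 = np.hypot(*(P[j] - P[i]).T)
            near = d0 <= sumr + att_range + gap_threshold
            i, j, sumr = i[near], j[near], sumr[near]
        dvec = P[j] - P[i]
        dist = np.hypot(dvec[:, 0], dvec[:, 1])
        overlap = sumr - dist
        mo = float(overlap.max()) if len(overlap) else 0.0
        report["max_overlap"] = max(mo, 0.0)
        if mo <= overlap_tolerance:
            break
        # unit vectors; coincident centers get a fixed symmetry-breaking axis
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = dvec[:, 0] / dist
            uy = dvec[:, 1] / dist
        ux[dist == 0] = 1.0
        uy[dist == 0] = 0.0
        # repulsion: pair separation grows by k_rep * depth;
        # attraction: pairs with a gap beyond the threshold close in weakly
        gap = -overlap
        step = np.where(
            overlap > 0,
            -0.5 * k_rep * overlap,
            np.where(
                (gap > gap_threshold) & (dist <= sumr + att_range),
                0.5 * k_att * (gap - gap_threshold),
                0.0,
            ),
        )
        fx, fy = ux * step, uy * step
        dx = np.bincount(i, fx, npts) - np.bincount(j, fx, npts)
        dy = np.bincount(i, fy, npts) - np.bincount(j, fy, npts)
        P[:, 0] += dx
        P[:, 1] += dy
        if clamp:
            np.clip(P[:, 0], dom.xmin + inset, dom.xmax - inset, out=P[:, 0])
            np.clip(P[:, 1], dom.ymin + inset, dom.ymax - inset, out=P[:, 1])
        report["iterations"] = it + 1
        report["displacements"].append(float(np.abs(dx).sum() + np.abs(dy).sum()))
    else:
        report["converged"] = report["max_overlap"] <= overlap_tolerance

    ep.pos[rows] = P
    ep.touch()
    ep.last_relax = report
    return ep


# ---------------------------------------------------------------------------
# growth and division


def grow_step(
    ep: Epithelium,
    cell_growth_rate: float,
    cell_max_size: float,
    rng: np.random.Generator | None = None,
) -> tuple[Epithelium, list[int]]:
    """One growth cycle.

    Precursors grow multiplicatively, capped at ``cell_max_size``; a precursor
    whose uncapped growth would exceed the cap divides into two equal daughters
    of radius cap/sqrt(2) (area of a cap-sized parent is conserved), displaced
    by a small random offset.  Specified cells grow toward their own
    target_radius and never divide.  Returns the ids of parents that divided.
    """
    if cell_growth_rate < 0:
        raise ParameterError(f"cell_growth_rate must be >= 0, got {cell_growth_rate}")
    if cell_max_size <= 0:
        raise ParameterError(f"cell_max_size must be positive, got {cell_max_size}")
    if rng is None:
        rng = np.random.default_rng(0)

    rows = ep.alive_rows()
    fate = ep.fate[rows]
    r = ep.radius[rows]
    prec = fate == int(Fate.PRECURSOR)
    spec = ~prec

    grown = r * (1.0 + cell_growth_rate)
    # precursors: cap at max size; strict > so rate 0 never triggers division
    divide = prec & (grown > cell_max_size)
    ep.radius[rows[prec]] = np.minimum(grown[prec], cell_max_size)
    # specified: approach own target, never shrink
    tgt = ep.target_radius[rows]
    ep.radius[rows[spec]] = np.where(
        r[spec] < tgt[spec], np.minimum(grown[spec], tgt[spec]), r[spec]
    )

    divided: list[int] = []
    if np.any(divide):
        dr = cell_max_size / math.sqrt(2.0)
        for row in rows[divide]:
            parent = int(ep.ids[row])
            theta = rng.uniform(0.0, 2.0 * math.pi)
            off = 0.3 * dr * np.array([math.cos(theta), math.sin(theta)])
            ppos = ep.pos[row].copy()
            ep.radius[row] = dr
            ep.pos[row] = ppos - off
            child = ep.add_cell(ppos + off, dr)
            ep.divisions.append((parent, child))
            divided.append(parent)
    ep.touch()
    return ep, divided


# ---------------------------------------------------------------------------
# persistence

_HEADER_PREFIX = "#EYEVOLVE-EPITHELIUM v1 "
_COLUMNS = ["id", "x", "y", "radius", "fate", "target_radius", "unit_id", "alive"]


def save_epithelium(ep: Epithelium, path) -> None:
    """Write the living cells as a versioned text cell table (diff-able CSV)."""
    header = {
        "version": 1,
        "domain": [ep.domain.xmin, ep.domain.xmax, ep.domain.ymin, ep.domain.ymax],
        "avg_cell_size": ep.avg_cell_size,
    }
    buf = io.StringIO()
    buf.write(_HEADER_PREFIX + json.dumps(header) + "\n")
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_COLUMNS)
    for row in ep.alive_rows():
        uid = int(ep.unit_id[row])
        w.writerow(
            [
                int(ep.ids[row]),
                repr(float(ep.pos[row, 0])),
                repr(float(ep.pos[row, 1])),
                repr(float(ep.radius[row])),
                Fate(int(ep.fate[row])).name,
                repr(float(ep.target_radius[row])),
                "" if uid < 0 else uid,
                1,
            ]
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_epithelium(path) -> Epithelium:
    """Load a cell table written by :func:`save_epithelium` (bit-exact)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_HEADER_PREFIX):
            raise FormatError(f"{path}: line 1: missing '{_HEADER_PREFIX.strip()}' header")
        try:
            meta = json.loads(first[len(_HEADER_PREFIX) :])
        except json.JSONDecodeError as e:
            raise FormatError(f"{path}: line 1: bad JSON header: {e}") from None
        reader = csv.reader(fh)
        try:
            cols = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: line 2: missing column header row") from None
        for required in _COLUMNS:
            if required not in cols:
                raise FormatError(f"{path}: line 2: missing column '{required}'")
        ix = {c: cols.index(c) for c in _COLUMNS}
        dom = Domain(*meta["domain"])
        ep = Epithelium(dom, float(meta["avg_cell_size"]))
        for lineno, rec in enumerate(reader, start=3):
            if not rec:
                continue
            try:
                uid_s = rec[ix["unit_id"]]
                ep.add_cell(
                    (float(rec[ix["x"]]), float(rec[ix["y"]])),
                    float(rec[ix["radius"]]),
                    fate=Fate[rec[ix["fate"]]],
                    target_radius=float(rec[ix["target_radius"]]),
                    unit_id=None if uid_s == "" else int(uid_s),
                    cell_id=int(rec[ix["id"]]),
                    alive=bool(int(rec[ix["alive"]])),
                )
            except (ValueError, KeyError, IndexError) as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from None
    ep.initial_count = ep.n_alive
    return ep


def neighbors(ep: Epithelium, cell_id: int, mode="contact", **kw):
    """Functional wrapper over :meth:`Epithelium.neighbors`."""
    return ep.neighbors(cell_id, mode, **kw)
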