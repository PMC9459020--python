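"""Deterministic toy tissues for tests and examples.

All fixtures build :class:`Epithelium` objects directly (no relaxation), so
their geometry is exact: hexagonal patches of touching equal circles, a
single equally spaced row, or one center cell with its six-cell contact ring.
"""

from __future__ import annotations

import math

import numpy as np

from .epithelium import Domain, Epithelium, ParameterError

FIXTURE_KINDS = ("hex_patch", "strip", "ring_unit")

_DEFAULT_RADIUS = 5.0


def _hex_spiral(n: int) -> list[tuple[float, float]]:
    """Hex-lattice spiral with unit spacing: center first, then ring by ring."""

    def cart(q: int, r: int) -> tuple[float, float]:
        return (q + r / 2.0, r * math.sqrt(3) / 2.0)

    out = [(0.0, 0.0)]
    ring = 1
    while len(out) < n:
        q, r = ring, 0
        for dq, dr in ((-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0), (0, 1)):
            for _ in range(ring):
                if len(out) < n:
                    out.append(cart(q, r))
                q, r = q + dq, r + dr
        ring += 1
    return out[:n]


def make_fixture(kind: str, size: int, seed: int = 0, radius: float = _DEFAULT_RADIUS) -> Epithelium:
    """Build a small deterministic epithelium.

    ``hex_patch``  size cells in a hexagonal packing of touching circles
    ``strip``      size cells in one row along x, equal spacing 2*radius
    ``ring_unit``  one center cell plus size-1 (max 6) touching ring cells
    """
    if size < 1 or size > 1000:
        raise ParameterError(f"fixture size must be in [1, 1000], got {size}")
    r = radius
    margin = 4 * r
    if kind == "hex_patch":
        pts = np.array(_hex_spiral(size)) * (2 * r)
    elif kind == "strip":
        pts = np.column_stack([np.arange(size) * 2 * r, np.zeros(size)]).astype(float)
    elif kind == "ring_unit":
        if size > 7:
            raise ParameterError(f"ring_unit holds at most 7 cells, got {size}")
        ang = np.arange(6) * math.pi / 3.0
        ring = np.column_stack([np.cos(ang), np.sin(ang)]) * (2 * r)
        pts = np.vstack([[0.0, 0.0], ring])[:size]
    else:
        raise ParameterError(f"unknown fixture kind {kind!r}; valid: {', '.join(FIXTURE_KINDS)}")
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    ep = Epithelium(Domain(lo[0], hi[0], lo[1], hi[1]), avg_cell_size=r)
    for p in pts:
        ep.add_cell(p, r)
    ep.initial_count = size
    return ep
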