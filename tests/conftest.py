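import numpy as np
import pytest

from eyevolve.epithelium import Domain, Epithelium


def grid_epithelium(n, avg=10.0, spacing=None, radius=None, jitter=0.0, seed=0):
    """Fast deterministic tissue on a square grid, no relaxation."""
    rng = np.random.default_rng(seed)
    m = int(np.ceil(np.sqrt(n)))
    spacing = 2 * avg if spacing is None else spacing
    radius = avg if radius is None else radius
    side = m * spacing
    ep = Epithelium(Domain(0, side, 0, side), avg)
    gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])[:n] * spacing + spacing / 2
    if jitter:
        pts = pts + rng.uniform(-jitter, jitter, pts.shape)
    for p in pts:
        ep.add_cell(p, radius)
    ep.initial_count = n
    return ep


@pytest.fixture
def grid_ep():
    return grid_epithelium


def brute_force_max_overlap(ep):
    """O(n^2) overlap oracle, independent of the package's spatial index."""
    rows = ep.alive_rows()
    worst = 0.0
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            i, j = rows[a], rows[b]
            d = float(np.hypot(*(ep.pos[i] - ep.pos[j])))
            worst = max(worst, ep.radius[i] + ep.radius[j] - d)
    return worst


def brute_force_overlap_sum(ep):
    rows = ep.alive_rows()
    total = 0.0
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            i, j = rows[a], rows[b]
            d = float(np.hypot(*(ep.pos[i] - ep.pos[j])))
            total += max(0.0, ep.radius[i] + ep.radius[j] - d)
    return total
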