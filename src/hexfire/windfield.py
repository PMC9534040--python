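"""Wind-gradient potentials from wind-direction maps.

Ember flight is steered by a scalar potential G: embers step from low to high
G values.  This module builds such potentials from maps of wind bearing
(degrees clockwise from grid-north, the direction the wind blows TOWARD).
Each cell is seeded with the planar ramp for its local bearing,

    G(cell) = x(cell) * sin(theta) - y(cell) * cos(theta),

using hexagon-center coordinates with y increasing downward (row 0 at the
top), so bearing 180 ("due south") yields G increasing with row index.  For
a spatially constant bearing this is exactly the ramp increasing downwind;
spatially varying fields are blended by optional neighbor-mean smoothing and
are one reasonable potential among many, not a physically exact wind model.
"""

from __future__ import annotations

import numpy as np

from .hexgrid import CellIndex, CellMap, center_arrays, neighbor_table, neighbors
from .landscape import hex_smooth

__all__ = ["build_gradient", "uphill_neighbor"]


def build_gradient(dirs: CellMap, smooth_iters: int = 0) -> CellMap:
    """Build a wind-gradient potential map from a wind-direction map.

    ``dirs`` holds per-cell bearings in degrees, clockwise from grid-north,
    in [0, 360).  ``smooth_iters`` passes of hex-neighborhood mean smoothing
    blend spatially varying fields; for a constant bearing the output is the
    exact planar ramp regardless of smoothing (smoothing a plane on interior
    cells preserves it; edge cells flatten slightly).
    """
    bearings = dirs.values
    if ((bearings < 0) | (bearings >= 360)).any():
        bad = bearings[(bearings < 0) | (bearings >= 360)][0]
        raise ValueError(f"bearing {bad} outside [0, 360)")
    grid = dirs.grid
    theta = np.deg2rad(bearings)
    x, y = center_arrays(grid)
    g = x * np.sin(theta) - y * np.cos(theta)
    if smooth_iters:
        g = hex_smooth(g, grid, smooth_iters)
    return CellMap(grid, g)


def uphill_neighbor(
    g: CellMap, cell: CellIndex, rng: np.random.Generator
) -> CellIndex:
    """The neighbor an ember takes when stepping along the wind gradient.

    Returns the in-bounds neighbor with maximal G; ties are broken uniformly
    at random.  At a local maximum (no neighbor exceeds G(cell)) the step
    degrades to a uniformly random in-bounds neighbor so embers never stall.
    """
    nbrs = neighbors(g.grid, cell)
    vals = np.array([g.values[n.row, n.col] for n in nbrs])
    here = g.values[cell[0], cell[1]]
    vmax = vals.max()
    if vmax > here:
        ties = np.flatnonzero(vals == vmax)
        pick = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
    else:
        pick = rng.integers(len(nbrs))
    return nbrs[int(pick)]


def gradient_neighbor_values(
    g: CellMap,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precomputed lookup for vectorized gradient climbing.

    Returns (nr, nc, valid, gvals) of shape (rows, cols, 6); ``gvals`` holds
    each neighbor's G with -inf at invalid (off-grid) slots.
    """
    nr, nc, valid = neighbor_table(g.grid)
    gvals = g.values[nr, nc]
    gvals[~valid] = -np.inf
    return nr, nc, valid, gvals
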