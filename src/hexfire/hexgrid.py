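"""Hexagonal lattice geometry and raster map I/O.

The simulator lives on a pointy-top hexagonal lattice stored in "odd-r offset"
coordinates: cells are addressed by (row, col) exactly like a rectangular
raster, with every odd row shifted half a cell to the right.  Row 0 is the top
of the map, matching the top-row-first order of ESRI ASCII grids, and the y
axis therefore increases downward.  Each cell has six equidistant immediate
neighbors (E, W, NE, NW, SE, SW); on a square grid the diagonal neighbors
would be farther away than the orthogonal ones, which is the usual argument
for hexagonal tessellations in spread models.

Maps are exchanged as ESRI ASCII grids (.asc), one raster cell per hexagon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import ClassVar, NamedTuple

import numpy as np

__all__ = [
    "GridSpec",
    "CellIndex",
    "CellMap",
    "neighbors",
    "hex_center",
    "neighbor_table",
    "neighbor_count",
    "read_ascii_grid",
    "write_ascii_grid",
]


class CellIndex(NamedTuple):
    """0-based (row, col) address of one hexagon."""

    row: int
    col: int


# Neighbor offsets for odd-r pointy-top hexes, by row parity.
# Order is fixed: E, W, NE, NW, SE, SW.
_OFFSETS_EVEN = ((0, 1), (0, -1), (-1, 0), (-1, -1), (1, 0), (1, -1))
_OFFSETS_ODD = ((0, 1), (0, -1), (-1, 1), (-1, 0), (1, 1), (1, 0))

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class GridSpec:
    """Dimensions of a hexagonal lattice in odd-r offset coordinates."""

    rows: int
    cols: int

    layout: ClassVar[str] = "odd-r offset, pointy-top"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.rows}x{self.cols}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def contains(self, cell: CellIndex) -> bool:
        r, c = cell
        return 0 <= r < self.rows and 0 <= c < self.cols


def neighbors(grid: GridSpec, cell: CellIndex) -> list[CellIndex]:
    """In-bounds immediate neighbors of ``cell``, in E, W, NE, NW, SE, SW order.

    Interior cells have exactly 6 neighbors; edge and corner cells have 3-5
    (2-3 for corners).  The lattice boundary is absorbing: neighbors outside
    the grid simply do not exist.
    """
    r, c = cell
    if not grid.contains(cell):
        raise IndexError(f"cell {tuple(cell)} outside {grid.rows}x{grid.cols} grid")
    offsets = _OFFSETS_ODD if r % 2 else _OFFSETS_EVEN
    out = []
    for dr, dc in offsets:
        nr, nc = r + dr, c + dc
        if 0 <= nr < grid.rows and 0 <= nc < grid.cols:
            out.append(CellIndex(nr, nc))
    return out


def hex_center(grid: GridSpec, cell: CellIndex) -> tuple[float, float]:
    """Planar center of a hexagon, unit spacing between adjacent centers.

    x = col + 0.5*(row % 2), y = row * sqrt(3)/2; y increases downward
    (row 0 at the top of the map).
    """
    if not grid.contains(cell):
        raise IndexError(f"cell {tuple(cell)} outside {grid.rows}x{grid.cols} grid")
    r, c = cell
    return (c + 0.5 * (r % 2), r * _SQRT3_2)


def center_arrays(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) center coordinates for every cell, as (rows, cols) arrays."""
    rr, cc = np.meshgrid(
        np.arange(grid.rows), np.arange(grid.cols), indexing="ij"
    )
    x = cc + 0.5 * (rr % 2)
    y = rr * _SQRT3_2
    return x.astype(float), y.astype(float)


def neighbor_table(grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized neighbor lookup tables.

    Returns (nr, nc, valid), each of shape (rows, cols, 6) in the fixed
    E, W, NE, NW, SE, SW direction order; ``valid`` is False where the
    neighbor would fall outside the grid (nr/nc are clipped there and must
    not be used).
    """
    rr, cc = np.meshgrid(
        np.arange(grid.rows), np.arange(grid.cols), indexing="ij"
    )
    odd = (rr % 2).astype(bool)
    nr = np.empty((grid.rows, grid.cols, 6), dtype=np.int64)
    nc = np.empty((grid.rows, grid.cols, 6), dtype=np.int64)
    for k in range(6):
        dr_e, dc_e = _OFFSETS_EVEN[k]
        dr_o, dc_o = _OFFSETS_ODD[k]
        nr[:, :, k] = rr + np.where(odd, dr_o, dr_e)
        nc[:, :, k] = cc + np.where(odd, dc_o, dc_e)
    valid = (
        (nr >= 0) & (nr < grid.rows) & (nc >= 0) & (nc < grid.cols)
    )
    nr = np.clip(nr, 0, grid.rows - 1)
    nc = np.clip(nc, 0, grid.cols - 1)
    return nr, nc, valid


def neighbor_count(mask: np.ndarray) -> np.ndarray:
    """Per-cell count of True neighbors of a boolean (rows, cols) mask.

    Used for the burning-neighbor count N in the contagion probability;
    values range 0-6.
    """
    p = np.pad(mask.astype(np.uint8), 1)
    # slices of the padded array, aligned on the unpadded grid
    e = p[1:-1, 2:]
    w = p[1:-1, :-2]
    up_c = p[:-2, 1:-1]
    up_l = p[:-2, :-2]
    up_r = p[:-2, 2:]
    dn_c = p[2:, 1:-1]
    dn_l = p[2:, :-2]
    dn_r = p[2:, 2:]
    n_even = e + w + up_c + up_l + dn_c + dn_l
    n_odd = e + w + up_c + up_r + dn_c + dn_r
    rows = np.arange(mask.shape[0])[:, None]
    return np.where(rows % 2 == 1, n_odd, n_even).astype(np.int64)


@dataclass
class CellMap:
    """One real value per lattice cell, row-major, with an optional nodata mask."""

    grid: GridSpec
    values: np.ndarray
    nodata: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid {self.grid.shape}"
            )
        if self.nodata is not None:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.grid.shape:
                raise ValueError("nodata mask shape mismatch")

    @classmethod
    def full(cls, grid: GridSpec, value: float) -> "CellMap":
        return cls(grid, np.full(grid.shape, float(value)))

    def copy(self) -> "CellMap":
        return CellMap(
            self.grid,
            self.values.copy(),
            None if self.nodata is None else self.nodata.copy(),
        )


class AsciiGridError(ValueError):
    """Raised for malformed ESRI ASCII grid files."""


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> CellMap:
    """Read an ESRI ASCII grid into a :class:`CellMap`.

    The dialect is the standard one: a header of ``ncols``, ``nrows``,
    ``xllcorner``, ``yllcorner``, ``cellsize`` and optionally
    ``NODATA_value`` (keys case-insensitive), followed by row-major values,
    top row first.  NODATA cells are flagged in the returned map's mask.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise AsciiGridError(
                    f"{path}:{i + 1}: non-numeric header value {parts[1]!r}"
                ) from None
            i += 1
        else:
            break
    for key in ("ncols", "nrows"):
        if key not in header:
            raise AsciiGridError(f"{path}: missing required header key {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata_value = header.get("nodata_value")

    rows_out: list[list[float]] = []
    for lineno in range(i, len(lines)):
        tokens = lines[lineno].split()
        if not tokens:
            continue
        try:
            rows_out.append([float(t) for t in tokens])
        except ValueError:
            bad = next(t for t in tokens if not _is_number(t))
            raise AsciiGridError(
                f"{path}:{lineno + 1}: non-numeric token {bad!r}"
            ) from None
    flat = [v for row in rows_out for v in row]
    if len(flat) != nrows * ncols:
        raise AsciiGridError(
            f"{path}: expected {nrows * ncols} values, found {len(flat)}"
        )
    values = np.array(flat, dtype=float).reshape(nrows, ncols)
    grid = GridSpec(nrows, ncols)
    nodata = None
    if nodata_value is not None:
        nodata = values == nodata_value
        if not nodata.any():
            nodata = np.zeros(grid.shape, dtype=bool)
    return CellMap(grid, values, nodata)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_ascii_grid(
    cmap: CellMap, path: str | Path, nodata_value: float = -9999.0
) -> None:
    """Write a :class:`CellMap` as an ESRI ASCII grid.

    ``write`` then ``read`` is the identity on values: floats are printed
    with ``repr``, which round-trips float64 exactly.
    """
    path = Path(path)
    grid = cmap.grid
    values = cmap.values
    has_nodata = cmap.nodata is not None and bool(cmap.nodata.any())
    with path.open("w") as fh:
        fh.write(f"ncols {grid.cols}\n")
        fh.write(f"nrows {grid.rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write("cellsize 1.0\n")
        if has_nodata:
            fh.write(f"NODATA_value {_fmt(nodata_value)}\n")
        for r in range(grid.rows):
            row = values[r]
            if has_nodata:
                toks = [
                    _fmt(nodata_value) if cmap.nodata[r, c] else _fmt(row[c])
                    for c in range(grid.cols)
                ]
            else:
                toks = [_fmt(v) for v in row]
            fh.write(" ".join(toks))
            fh.write("\n")


def _fmt(v: float) -> str:
    if float(v).is_integer() and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))
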