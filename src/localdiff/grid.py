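"""Regular analysis grid of 100 m square cells in projected meters.

Cells are half-open ``[x0, x0+s) x [y0, y0+s)`` so every point belongs to at
most one cell.  A boolean ``active`` mask supports non-rectangular domains
(e.g. several monitored neighborhoods inside a bounding rectangle); cell ids
are ``row * ncols + col`` and remain stable regardless of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box


@dataclass(frozen=True)
class Grid:
    x0: float
    y0: float
    ncols: int
    nrows: int
    cell_size: float = 100.0
    active: np.ndarray = field(default=None, repr=False)  # (nrows, ncols) bool

    def __post_init__(self):
        if self.ncols <= 0 or self.nrows <= 0 or self.cell_size <= 0:
            raise ValueError("grid dimensions and cell size must be positive")
        if self.active is None:
            object.__setattr__(
                self, "active", np.ones((self.nrows, self.ncols), dtype=bool)
            )
        elif self.active.shape != (self.nrows, self.ncols):
            raise ValueError("active mask shape must be (nrows, ncols)")

    @property
    def n_cells(self) -> int:
        return int(self.active.sum())

    def cell_ids(self) -> np.ndarray:
        """Ids of active cells, ascending."""
        return np.flatnonzero(self.active.ravel())

    def cell_origin(self, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ids = np.asarray(ids)
        row, col = divmod(ids, self.ncols)
        return self.x0 + col * self.cell_size, self.y0 + row * self.cell_size

    def cell_center(self, ids: np.ndarray) -> np.ndarray:
        x, y = self.cell_origin(ids)
        h = self.cell_size / 2.0
        return np.column_stack([x + h, y + h])

    def cell_polygon(self, cell_id: int):
        x, y = self.cell_origin(np.asarray([cell_id]))
        s = self.cell_size
        return box(float(x[0]), float(y[0]), float(x[0]) + s, float(y[0]) + s)

    def locate(self, x, y) -> np.ndarray:
        """Cell id for each point; -1 for points outside any active cell.

        Half-open convention: a point on a cell's low edge belongs to that
        cell, a point on the high edge belongs to the neighbour.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        ids = np.where(inside, row * self.ncols + col, -1)
        act = np.zeros(ids.shape, dtype=bool)
        act[inside] = self.active.ravel()[ids[inside]]
        return np.where(act, ids, -1)

    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_size,
            self.y0 + self.nrows * self.cell_size,
        )
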