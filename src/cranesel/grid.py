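"""Minimal regular-grid raster container.

Rasters are stored as 2-D numpy arrays on an axis-aligned grid in projected
meters. Row 0 is the *southernmost* row (y increases with row index), which
keeps world-to-index arithmetic sign-free. This is the in-memory container
used for land-use, ownership, channel-proportion, and bank-height layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AnnotationError


@dataclass
class Raster:
    """A single-band raster on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (ny, nx)
        Cell values; row 0 is the southernmost row.
    x0, y0 : float
        World coordinates of the grid's lower-left corner (m).
    cell : float
        Cell size (m), square cells.
    """

    data: np.ndarray
    x0: float
    y0: float
    cell: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def ny(self) -> int:
        return self.data.shape[0]

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple:
        """(xmin, ymin, xmax, ymax) of the gridded extent."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell,
            self.y0 + self.ny * self.cell,
        )

    def xy_to_rc(self, x, y):
        """Row/column indices of the cells containing points (x, y)."""
        c = np.floor((np.asarray(x, float) - self.x0) / self.cell).astype(np.int64)
        r = np.floor((np.asarray(y, float) - self.y0) / self.cell).astype(np.int64)
        return r, c

    def contains_xy(self, x, y):
        r, c = self.xy_to_rc(x, y)
        return (r >= 0) & (r < self.ny) & (c >= 0) & (c < self.nx)

    def sample(self, x, y):
        """Values at points (x, y); raises AnnotationError off-grid."""
        r, c = self.xy_to_rc(x, y)
        bad = (r < 0) | (r >= self.ny) | (c < 0) | (c >= self.nx)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise AnnotationError(
                f"point ({np.asarray(x).flat[i]:.1f}, {np.asarray(y).flat[i]:.1f}) "
                "is outside the raster extent"
            )
        return self.data[r, c]

    def cell_centers(self):
        """(X, Y) arrays of cell-center coordinates, shape (ny, nx)."""
        xc = self.x0 + (np.arange(self.nx) + 0.5) * self.cell
        yc = self.y0 + (np.arange(self.ny) + 0.5) * self.cell
        return np.meshgrid(xc, yc)

    def like(self, data: np.ndarray) -> "Raster":
        """A new raster on the same grid with different data."""
        if data.shape != self.data.shape:
            raise ValueError("shape mismatch")
        return Raster(data, self.x0, self.y0, self.cell)
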