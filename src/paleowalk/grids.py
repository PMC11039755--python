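"""Raster geometry and elevation containers.

All synthetic runs use planar grids with distances in kilometres and
cell-centred registration.  Row 0 is the northern (top) edge, so the y
coordinate decreases with increasing row index.  Geographic (degree) grids are
accepted at I/O but every in-memory computation here assumes planar km.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import InvalidInputError

#: Row/col offsets of the 8-connected (D8) neighbourhood, row-major order.
D8_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

#: Centre-to-centre distance of each D8 neighbour, in cell units.
D8_DISTANCES = np.array([np.sqrt(2.0), 1.0, np.sqrt(2.0), 1.0, 1.0, np.sqrt(2.0), 1.0, np.sqrt(2.0)])

SECONDS_PER_YEAR = 365.25 * 24 * 3600.0


class CoordinateKind(str, Enum):
    PLANAR = "planar"
    GEOGRAPHIC = "geographic"


@dataclass(frozen=True)
class GridGeometry:
    """Shape, resolution and placement of a raster.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; at least 8 each.
    cell_size
        Cell edge length in km (planar mode) or degrees (geographic mode).
    origin
        (x, y) of the **centre** of the top-left cell (cell-centred
        registration, row 0 = northern edge).
    kind
        Planar km grid (default for all synthetic runs) or geographic degrees.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    kind: CoordinateKind = CoordinateKind.PLANAR

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise InvalidInputError(
                f"grid must be at least 8x8, got {self.n_rows}x{self.n_cols}"
            )
        if self.cell_size <= 0:
            raise InvalidInputError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        """Cell area in km² (planar mode)."""
        return self.cell_size * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        x = x0 + np.arange(self.n_cols) * self.cell_size
        y = y0 - np.arange(self.n_rows) * self.cell_size
        return np.meshgrid(x, y)

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Containing cell of a continuous position (clipped to the grid)."""
        x0, y0 = self.origin
        col = int(round((x - x0) / self.cell_size))
        row = int(round((y0 - y) / self.cell_size))
        return (
            min(max(row, 0), self.n_rows - 1),
            min(max(col, 0), self.n_cols - 1),
        )

    def rowcol_to_xy(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + col * self.cell_size, y0 - row * self.cell_size)

    def same_as(self, other: "GridGeometry") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
            and self.kind == other.kind
        )


def check_same_geometry(a: GridGeometry, b: GridGeometry, what: str = "raster") -> None:
    if not a.same_as(b):
        raise InvalidInputError(f"{what} geometry mismatch: {a} vs {b}")


@dataclass
class ElevationGrid:
    """Elevation raster in metres on a :class:`GridGeometry`."""

    geometry: GridGeometry
    z: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.shape != self.geometry.shape:
            raise InvalidInputError(
                f"elevation shape {self.z.shape} does not match geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.z)):
            raise InvalidInputError("elevation must be finite everywhere")

    def copy(self) -> "ElevationGrid":
        return ElevationGrid(self.geometry, self.z.copy())
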