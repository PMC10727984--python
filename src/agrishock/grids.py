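"""Minimal georeferenced raster carrier used by every stage of the pipeline.

A :class:`GridField` is a 2-D numeric layer plus a validity mask and a
north-up affine geotransform.  Cells are indexed row-major from the
north-west corner; latitude decreases with row index, longitude increases
with column index.  All layers of one analysis share a single grid, and
every binary operation checks alignment explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeoTransform", "GridField", "GridAlignmentError"]


class GridAlignmentError(ValueError):
    """Raised when two layers do not share shape and geotransform."""


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine transform: (lon0, cell, 0, lat0, 0, -cell) in GDAL order.

    ``lon0``/``lat0`` are the coordinates of the north-west corner of the
    north-west cell; ``cell_size_deg`` is the (square) cell edge in degrees.
    """

    lon0: float
    lat0: float
    cell_size_deg: float

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        lat = self.lat0 - (np.asarray(row) + 0.5) * self.cell_size_deg
        lon = self.lon0 + (np.asarray(col) + 0.5) * self.cell_size_deg
        return lat, lon


@dataclass
class GridField:
    """A 2-D layer with nodata mask and geotransform.

    ``values`` is float (or int) ndarray of shape (rows, cols); ``mask`` is
    True where the cell holds valid data.  Masked cells keep whatever fill
    value ``values`` carries and are never read by downstream operations.
    """

    values: np.ndarray
    transform: GeoTransform
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("GridField values must be 2-D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def aligned_with(self, other: "GridField") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def require_aligned(self, other: "GridField") -> None:
        if not self.aligned_with(other):
            raise GridAlignmentError(
                f"grids not aligned: {self.shape}/{self.transform} vs "
                f"{other.shape}/{other.transform}"
            )

    def with_values(self, values: np.ndarray, name: str | None = None) -> "GridField":
        """New field on the same grid and mask."""
        return GridField(
            np.asarray(values),
            self.transform,
            self.mask.copy(),
            self.name if name is None else name,
        )

    def masked(self) -> np.ndarray:
        """Valid values as a 1-D array (row-major order of valid cells)."""
        return self.values[self.mask]

    def copy(self) -> "GridField":
        return GridField(self.values.copy(), self.transform, self.mask.copy(), self.name)
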