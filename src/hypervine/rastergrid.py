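"""Local metric raster frame (meters, pixel-center convention, north-up).

No geodetic CRS: x grows east with column index, y grows north, row 0 is
the northern edge.  A pixel belongs to a polygon iff its center does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = ["RasterGrid"]


@dataclass(frozen=True)
class RasterGrid:
    ny: int
    nx: int
    gsd: float
    x0: float = 0.0  # west edge (m)
    y1: float | None = None  # north edge (m); defaults to ny * gsd

    def __post_init__(self) -> None:
        if self.y1 is None:
            object.__setattr__(self, "y1", self.ny * self.gsd)
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinates, each of shape (ny, nx)."""
        x = self.x0 + (np.arange(self.nx) + 0.5) * self.gsd
        y = self.y1 - (np.arange(self.ny) + 0.5) * self.gsd
        return np.meshgrid(x, y)

    def mask_for_polygon(self, poly: Polygon, erode_pixels: int = 0) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside ``poly``.

        ``erode_pixels`` shrinks the polygon by that many pixel widths
        first (used to drop boundary mixels when sampling panels).
        """
        if erode_pixels:
            poly = poly.buffer(-erode_pixels * self.gsd)
            if poly.is_empty:
                return np.zeros(self.shape, dtype=bool)
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.floor((minx - self.x0) / self.gsd)) - 1)
        c1 = min(self.nx, int(np.ceil((maxx - self.x0) / self.gsd)) + 1)
        r0 = max(0, int(np.floor((self.y1 - maxy) / self.gsd)) - 1)
        r1 = min(self.ny, int(np.ceil((self.y1 - miny) / self.gsd)) + 1)
        out = np.zeros(self.shape, dtype=bool)
        if c0 >= c1 or r0 >= r1:
            return out
        x = self.x0 + (np.arange(c0, c1) + 0.5) * self.gsd
        y = self.y1 - (np.arange(r0, r1) + 0.5) * self.gsd
        xx, yy = np.meshgrid(x, y)
        out[r0:r1, c0:c1] = shapely.contains_xy(poly, xx, yy)
        return out

    def intersects_raster(self, poly: Polygon) -> bool:
        extent = Polygon(
            [
                (self.x0, self.y1 - self.ny * self.gsd),
                (self.x0 + self.nx * self.gsd, self.y1 - self.ny * self.gsd),
                (self.x0 + self.nx * self.gsd, self.y1),
                (self.x0, self.y1),
            ]
        )
        return extent.intersects(poly)
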