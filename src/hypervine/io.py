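"""File formats: multi-band TIFF rasters, GeoJSON vectors, CSV tables.

Rasters live in a local metric frame (meters, north-up, pixel-center
convention), so no geodetic CRS is attached; the grid geometry and the
band-center wavelengths travel in the TIFF ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

from .rastergrid import RasterGrid

__all__ = [
    "write_raster",
    "read_raster",
    "write_geojson",
    "read_geojson",
]


def write_raster(
    path: str | Path,
    array: np.ndarray,
    raster: RasterGrid,
    wavelengths: np.ndarray | None = None,
    description: str = "",
) -> None:
    """Write a (B, ny, nx) or (ny, nx) array as TIFF with geometry metadata."""
    arr = np.asarray(array)
    meta = {
        "gsd_m": raster.gsd,
        "x0_m": raster.x0,
        "y1_m": raster.y1,
        "ny": raster.ny,
        "nx": raster.nx,
        "description": description,
    }
    if wavelengths is not None:
        meta["wavelengths_nm"] = [float(w) for w in wavelengths]
    tifffile.imwrite(str(path), arr, description=json.dumps(meta))


def read_raster(path: str | Path) -> tuple[np.ndarray, RasterGrid, dict]:
    """Read a raster written by :func:`write_raster`."""
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    raster = RasterGrid(
        ny=int(meta.get("ny", arr.shape[-2])),
        nx=int(meta.get("nx", arr.shape[-1])),
        gsd=float(meta.get("gsd_m", 1.0)),
        x0=float(meta.get("x0_m", 0.0)),
        y1=float(meta.get("y1_m", arr.shape[-2] * meta.get("gsd_m", 1.0))),
    )
    return arr, raster, meta


def write_geojson(path: str | Path, features: list[tuple[object, dict]]) -> None:
    """Write (shapely geometry, properties) pairs as a FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(fc, indent=1, sort_keys=True))


def read_geojson(path: str | Path) -> list[tuple[object, dict]]:
    fc = json.loads(Path(path).read_text())
    return [(shape(f["geometry"]), f.get("properties", {})) for f in fc["features"]]
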