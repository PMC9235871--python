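"""Narrowband vegetation index registry.

The registry reproduces, formula-for-formula, the published table of 38
narrowband index rows computed in the original workflow (one row — NRER —
is printed twice with an identical formula and is collapsed to a single
named entry, leaving 37 distinct indices).  Formulas are implemented
verbatim as printed, including the places where the printed form departs
from the literature's canonical variant (PRI band order, the NDRE band
pair, the MTCIvar denominator, the NRI bands, the EVI "+1" outside the
ratio, and the additive REP expression); this library reproduces a
specific workflow, not the index literature.

Wavelength symbols like ``R_660`` resolve to the nearest band center
within the grid FWHM; on the default 50-band grid every printed
wavelength resolves (note 660 and 663 nm land on the same 663.3 nm
center).  ``D_λ`` denotes the first-derivative spectrum; derivative
windows ``[a, b]`` take the max or sum of D over **all** bands whose
centers lie in the closed nm interval ("window" mode, the default), or
just the two named bands ("pair" mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .bands import BandGrid, nearest_band
from .rastergrid import RasterGrid
from .segmentation import ROIPolygon
from .spectra import SpectralDataset

__all__ = [
    "VIDefinition",
    "REGISTRY",
    "index_names",
    "first_derivative",
    "compute_index",
    "compute_indices",
    "compute_all",
    "registry_frame",
]

log = logging.getLogger(__name__)


def first_derivative(spectrum: np.ndarray, grid: BandGrid) -> np.ndarray:
    """First derivative of reflectance with respect to wavelength (nm⁻¹).

    Central differences in the interior, one-sided at the endpoints;
    identically zero for a constant spectrum.  Works on a single spectrum
    (B,) or a stack (..., B) along the last axis.
    """
    r = np.asarray(spectrum, dtype=float)
    lam = grid.centers
    if r.shape[-1] != lam.size:
        raise ValueError("spectrum length must equal the grid length")
    if lam.size < 3:
        raise ValueError("need at least 3 bands for a derivative spectrum")
    d = np.empty_like(r)
    d[..., 1:-1] = (r[..., 2:] - r[..., :-2]) / (lam[2:] - lam[:-2])
    d[..., 0] = (r[..., 1] - r[..., 0]) / (lam[1] - lam[0])
    d[..., -1] = (r[..., -1] - r[..., -2]) / (lam[-1] - lam[-2])
    return d


@dataclass(frozen=True)
class VIDefinition:
    """One registry row: name, printed formula, and its evaluator.

    ``evaluator`` receives ``r``, a resolver mapping a wavelength in nm to
    the reflectance column at the nearest band, and must return the index
    value(s).  Derivative indices instead carry the window bounds and an
    operation ("max"/"sum") applied to the first-derivative spectrum.
    """

    name: str
    full_name: str
    group: str
    formula: str
    wavelengths: tuple[float, ...]
    evaluator: Callable[[Callable[[float], np.ndarray]], np.ndarray] | None = None
    deriv_window: tuple[float, float] | None = None
    deriv_op: str | None = None


def _nd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a - b) / (a + b)


_R = [
    ("NDVI1", "Normalized difference vegetation index", "NIR, VIS",
     "(R850-R660)/(R850+R660)", (850, 660), lambda r: _nd(r(850), r(660))),
    ("NDVI2", "Normalized difference vegetation index", "NIR, VIS",
     "(R835-R660)/(R835+R660)", (835, 660), lambda r: _nd(r(835), r(660))),
    ("NDVI3", "Normalized difference vegetation index", "NIR, VIS",
     "(R850-R660)/(R850+R660)", (850, 660), lambda r: _nd(r(850), r(660))),
    ("GNDVI1", "Green NDVI", "NIR, VIS",
     "(R850-R540)/(R850+R540)", (850, 540), lambda r: _nd(r(850), r(540))),
    ("GNDVI2", "Green NDVI", "NIR, VIS",
     "(R780-R550)/(R780+R550)", (780, 550), lambda r: _nd(r(780), r(550))),
    ("SAVI", "Soil-adjusted vegetation index", "NIR, VIS",
     "(1+0.5)x(R802-R660)/(R802+R660+0.5)", (802, 660),
     lambda r: 1.5 * (r(802) - r(660)) / (r(802) + r(660) + 0.5)),
    ("RENDVI", "Red edge normalized difference vegetation index", "NIR, RE",
     "(R850-R680)/(R850+R680)", (850, 680), lambda r: _nd(r(850), r(680))),
    ("NDRE", "Normalized difference nir/red edge index", "NIR, RE",
     "(R770-R750)/(R770+R750)", (770, 750), lambda r: _nd(r(770), r(750))),
    ("NRER", "Nir-re-red normalized difference vegetation index", "NIR, RE, VIS",
     "(R850-R695)/(R695+R660)", (850, 695, 660),
     lambda r: (r(850) - r(695)) / (r(695) + r(660))),
    ("TCARI", "Transformed chlorophyll absorption ratio", "NIR, RE, VIS",
     "3x[(R695-R663)-0.2(R695-R540)x(R695/R663)]", (695, 663, 540),
     lambda r: 3.0 * ((r(695) - r(663)) - 0.2 * (r(695) - r(540)) * (r(695) / r(663)))),
    ("MTVI1", "Modified triangular vegetation index", "NIR, RE, VIS",
     "1.2x(1.2(R800-R540)-2.5(R660-R540))", (800, 660, 540),
     lambda r: 1.2 * (1.2 * (r(800) - r(540)) - 2.5 * (r(660) - r(540)))),
    ("MTVI2", "Modified triangular vegetation index", "NIR, RE, VIS",
     "1.2x(1.2(R800-R550)-2.5(R670-R550))", (800, 670, 550),
     lambda r: 1.2 * (1.2 * (r(800) - r(550)) - 2.5 * (r(670) - r(550)))),
    ("EVI", "Enhanced vegetation index", "NIR, RE, VIS",
     "2.5x(R850-R660)/(R850+6xR660-7.5xR505)+1", (850, 660, 505),
     lambda r: 2.5 * (r(850) - r(660)) / (r(850) + 6.0 * r(660) - 7.5 * r(505)) + 1.0),
    ("LCI", "Leaf chlorophyll index", "NIR, RE, VIS",
     "(R850-R710)/(R850+R680)", (850, 710, 680),
     lambda r: (r(850) - r(710)) / (r(850) + r(680))),
    ("MTCIvar", "Meris terrestrial chlorophyll index", "NIR, RE",
     "(R850-R680)/(R680+R660)", (850, 680, 660),
     lambda r: (r(850) - r(680)) / (r(680) + r(660))),
    ("NRI", "Nitrogen reflectance index", "NIR, RE",
     "(R555-R550)/(R555+R550)", (555, 550), lambda r: _nd(r(555), r(550))),
    ("PRI", "Photochemical reflectance index", "NIR, RE",
     "(R570-R530)/(R570+R530)", (570, 530), lambda r: _nd(r(570), r(530))),
    ("SPVI", "Spectral polygon vegetation index", "NIR, RE, VIS",
     "0.4x[3.7x(R800-R670)-1.2(R530-R670)]", (800, 670, 530),
     lambda r: 0.4 * (3.7 * (r(800) - r(670)) - 1.2 * (r(530) - r(670)))),
    ("SR710", "Simple ratio 710", "RE", "R750/R710", (750, 710),
     lambda r: r(750) / r(710)),
    ("SR680", "Simple ratio 680", "RE", "R800/R680", (800, 680),
     lambda r: r(800) / r(680)),
    ("RVI", "Ratio vegetation index", "NIR, VIS", "R810/R660", (810, 660),
     lambda r: r(810) / r(660)),
    ("VOG1", "Vogelmann index", "RE", "R745/R720", (745, 720),
     lambda r: r(745) / r(720)),
    ("GM", "Gitelson and Merzlyak index", "RE, VIS", "R750/R550", (750, 550),
     lambda r: r(750) / r(550)),
    ("MNDm", "Modified normalized difference", "NIR, RE, VIS",
     "(R750-R705)/(R750+R705-2xR508)", (750, 705, 508),
     lambda r: (r(750) - r(705)) / (r(750) + r(705) - 2.0 * r(508))),
    ("NDRE2", "Normalized difference nir/red edge index", "NIR, RE, VIS",
     "(R795-R720)/(R795+R720)", (795, 720), lambda r: _nd(r(795), r(720))),
    ("MCARI2", "Modified chlorophyll absorption in reflectance", "NIR, RE, VIS",
     "(R750-R705)-0.2(R750-R550)x(R750/R705)", (750, 705, 550),
     lambda r: (r(750) - r(705)) - 0.2 * (r(750) - r(550)) * (r(750) / r(705))),
    ("TVI", "Triangular vegetation index", "NIR, RE, VIS",
     "0.5x[120x(R750-R550)-200(R670-R550)]", (750, 670, 550),
     lambda r: 0.5 * (120.0 * (r(750) - r(550)) - 200.0 * (r(670) - r(550)))),
    ("EVI2", "Enhanced vegetation index 2", "NIR, RE, VIS",
     "2.5x(R800-R670)/(R800+6xR670-7.5xR508)+1", (800, 670, 508),
     lambda r: 2.5 * (r(800) - r(670)) / (r(800) + 6.0 * r(670) - 7.5 * r(508)) + 1.0),
    ("REP", "Red edge position index", "NIR, RE, VIS",
     "700+(45xR670+R778)/2-(R850)/(R735-R695)", (670, 778, 850, 735, 695),
     lambda r: 700.0 + (45.0 * r(670) + r(778)) / 2.0 - r(850) / (r(735) - r(695))),
]

_D = [
    ("maxR", "1st Derivative Max RED index", "dHVI-VIS", "Max[D660,D680]", (660, 680), "max"),
    ("sumR", "1st Derivative Sum RED index", "dHVI-VIS", "Sum[D660,D680]", (660, 680), "sum"),
    ("maxRE", "1st Derivative Max RE index", "dHVI-RE", "Max[D690,D700]", (690, 700), "max"),
    ("sumRE", "1st Derivative Sum RE index", "dHVI-RE", "Sum[D690,D700]", (690, 700), "sum"),
    ("maxLARE", "1st Derivative Max LARE index", "dHVI-RE", "Max[D690,D710]", (690, 710), "max"),
    ("sumLARE", "1st Derivative Sum LARE index", "dHVI-RE", "Sum[D690,D710]", (690, 710), "sum"),
    ("maxNIR", "1st Derivative Max NIR index", "dHVI-NIR", "Max[D790,D840]", (790, 840), "max"),
    ("sumNIR", "1st Derivative Sum NIR index", "dHVI-NIR", "Sum[D790,D840]", (790, 840), "sum"),
]

REGISTRY: dict[str, VIDefinition] = {}
for name, full, group, formula, wl, fn in _R:
    REGISTRY[name] = VIDefinition(name, full, group, formula, tuple(float(w) for w in wl),
                                  evaluator=fn)
for name, full, group, formula, (a, b), op in _D:
    REGISTRY[name] = VIDefinition(name, full, group, formula, (float(a), float(b)),
                                  deriv_window=(float(a), float(b)), deriv_op=op)

# The printed table has 38 rows; NRER appears twice with the same formula.
N_PRINTED_ROWS = 38


def index_names() -> list[str]:
    return list(REGISTRY)


def registry_frame() -> pd.DataFrame:
    """Audit dump of the formula table."""
    return pd.DataFrame(
        [
            {
                "name": d.name,
                "full_name": d.full_name,
                "group": d.group,
                "formula": d.formula,
                "wavelengths_nm": " ".join(f"{w:g}" for w in d.wavelengths),
            }
            for d in REGISTRY.values()
        ]
    )


def _evaluate(
    d: VIDefinition,
    values: np.ndarray,
    grid: BandGrid,
    dhvi_mode: str = "window",
) -> np.ndarray:
    """Evaluate one index on a (N, B) stack; returns (N,) with NaN where undefined."""
    if d.deriv_window is not None:
        deriv = first_derivative(values, grid)
        a, b = d.deriv_window
        if dhvi_mode == "window":
            cols = np.nonzero((grid.centers >= a) & (grid.centers <= b))[0]
            if cols.size == 0:
                cols = np.array([nearest_band(grid, a), nearest_band(grid, b)])
        elif dhvi_mode == "pair":
            cols = np.array([nearest_band(grid, a), nearest_band(grid, b)])
        else:
            raise ValueError(f"unknown dhvi_mode {dhvi_mode!r}")
        sub = deriv[..., cols]
        return sub.max(axis=-1) if d.deriv_op == "max" else sub.sum(axis=-1)

    def r(wavelength: float) -> np.ndarray:
        return values[..., nearest_band(grid, wavelength)]

    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(d.evaluator(r), dtype=float)
    bad = ~np.isfinite(out)
    if bad.any():
        log.warning("index %s undefined for %d spectra (zero denominator -> NA)",
                    d.name, int(bad.sum()))
        out = np.where(bad, np.nan, out)
    return out


def compute_index(
    name: str,
    spectrum: np.ndarray,
    grid: BandGrid,
    dhvi_mode: str = "window",
) -> float:
    """Evaluate a single registered index on one spectrum."""
    if name not in REGISTRY:
        raise KeyError(f"unknown index {name!r}; registered: {', '.join(REGISTRY)}")
    values = np.asarray(spectrum, dtype=float)[None, :]
    return float(_evaluate(REGISTRY[name], values, grid, dhvi_mode)[0])


def compute_indices(
    values: np.ndarray, grid: BandGrid, dhvi_mode: str = "window"
) -> pd.DataFrame:
    """All registered indices for a stack of spectra (N, B) → (N, n_indices)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(
        {name: _evaluate(d, values, grid, dhvi_mode) for name, d in REGISTRY.items()}
    )


def compute_all(
    dataset: SpectralDataset | None = None,
    grid: BandGrid | None = None,
    *,
    cube: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    rois: list[ROIPolygon] | None = None,
    raster: RasterGrid | None = None,
    aggregation: str = "index-mean",
    dhvi_mode: str = "window",
) -> pd.DataFrame:
    """Per-vine table of every registered index.

    Two aggregation modes mirror the two places an average can be taken:

    - ``"index-mean"`` (the study protocol): indices computed per masked
      pixel inside each polygon, then averaged (NaN pixels excluded; a
      vine with only NaN pixels yields NA with a warning).  Requires
      ``cube``/``mask``/``rois``/``raster``.
    - ``"spectrum-mean"``: indices evaluated on each vine's mean
      spectrum.  Requires ``dataset``.

    Returns a frame with ``vine_id`` first, one column per index.
    """
    if grid is None:
        raise ValueError("grid is required")
    if aggregation == "spectrum-mean":
        if dataset is None:
            raise ValueError("spectrum-mean aggregation requires a SpectralDataset")
        out = compute_indices(dataset.values, grid, dhvi_mode)
        out.insert(0, "vine_id", dataset.vine_id)
        return out
    if aggregation != "index-mean":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if cube is None or mask is None or rois is None or raster is None:
        raise ValueError("index-mean aggregation requires cube, mask, rois and raster")
    rows = []
    for roi in rois:
        sel = raster.mask_for_polygon(roi.polygon) & mask
        if not sel.any():
            log.warning("vine %s: no masked pixels, skipped in index table", roi.vine_id)
            continue
        per_pixel = compute_indices(cube[:, sel].T, grid, dhvi_mode)
        means = per_pixel.mean(axis=0, skipna=True)  # NA pixels excluded per index
        if means.isna().any():
            log.warning("vine %s: all-NA pixels for %s", roi.vine_id,
                        list(means.index[means.isna()]))
        rows.append({"vine_id": roi.vine_id, **means.to_dict()})
    return pd.DataFrame(rows)
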