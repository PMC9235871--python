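"""Synthetic vineyard scene rendering.

Produces what the imaging chain would deliver over a small vineyard block:
a DN hypercube, a digital surface model, reference reflectance panels, and
the truth layers (class mask, per-pixel vine id, true reflectance) that
make every downstream stage testable.  The block follows the study
geometry: north–south vine rows at 2.4 m × 1 m (between-/within-row)
spacing, vertical-shoot-positioned canopies rendered as raised strips over
a soil/grass inter-row, five reference panels (2/9/25/50/88 % reflectance)
in a southern margin, and a configurable ground sampling distance
(~2 cm/pixel in the flown campaign; coarser defaults keep simulations
light).

Radiometry: per band, radiance is true reflectance times a smooth
solar-like illumination curve, and ``DN = round(L/gain + dark + noise)``.
With ``noise_free=True`` the additive DN noise, the canopy multiplicative
noise and the DN rounding are all disabled, giving an exact
reflectance→DN→reflectance oracle for the calibration round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .bands import BandGrid, make_band_grid
from .canopy import CanopyForwardModel, canopy_reflectance
from .radiometry import PANEL_REFLECTANCES, RadiometricConfig
from .rastergrid import RasterGrid
from .segmentation import ROIPolygon
from .spectra import SpectralDataset
from .traits import TraitSpec

__all__ = [
    "SceneLayout",
    "SceneRaster",
    "LayoutError",
    "render_scene",
    "solar_illumination",
    "soil_spectrum",
    "grass_spectrum",
    "CLASS_CODES",
]

CLASS_CODES = {"soil": 0, "grass": 1, "canopy": 2, "shadow": 3, "panel": 4}


class LayoutError(ValueError):
    """The requested layout cannot accommodate the vines or panels."""


@dataclass(frozen=True)
class SceneLayout:
    """Geometry and radiometry of the rendered block."""

    n_rows: int = 6
    vines_per_row: int = 10
    row_spacing: float = 2.4      # m between rows (east-west)
    vine_spacing: float = 1.0     # m within row (north-south)
    gsd: float = 0.05             # m / pixel
    canopy_width: float = 0.6     # m, full canopy strip width
    shadow_width: float = 0.16    # m, shaded-leaf strip on the east side
    canopy_height: float = 1.8    # m above ground
    margin: float = 1.6           # m around the planting
    panel_strip: float = 1.6      # m, southern strip holding the panels
    panel_size: float = 0.5       # m, panel side
    grass_strip_width: float = 1.0  # m of grass centered in each inter-row
    ground_elevation: float = 100.0  # m
    shade_factor: float = 0.25    # shadow spectrum = canopy spectrum x factor
    roi_size: float = 0.8         # m, extraction square side
    dn_full_scale: float = 50000.0  # counts at reflectance 1 under unit illumination
    dark_counts: float = 100.0
    dn_noise_sd: float = 20.0     # counts
    quantize: bool = True
    flat_illumination: bool = False  # unit irradiance instead of the solar curve

    @property
    def width(self) -> float:
        return 2 * self.margin + (self.n_rows - 1) * self.row_spacing

    @property
    def height(self) -> float:
        return self.panel_strip + 2 * self.margin + self.vines_per_row * self.vine_spacing

    def noise_free(self) -> "SceneLayout":
        return replace(self, dn_noise_sd=0.0, quantize=False)


@dataclass
class SceneRaster:
    """Rendered scene: sensor products plus generator truth."""

    band_grid: BandGrid
    raster: RasterGrid
    dn_cube: np.ndarray              # (B, ny, nx)
    dsm: np.ndarray                  # (ny, nx), m
    ground_elevation: np.ndarray     # (ny, nx), m
    class_mask: np.ndarray           # (ny, nx), CLASS_CODES
    panel_specs: list[tuple[Polygon, float]]
    vine_points: pd.DataFrame        # vine_id, x, y
    rois: list[ROIPolygon]
    radiometry: RadiometricConfig
    reflectance_truth: np.ndarray    # (B, ny, nx)
    vine_id_map: np.ndarray          # (ny, nx), -1 = background
    canopy_spectra: SpectralDataset
    layout: SceneLayout

    @property
    def gsd(self) -> float:
        return self.raster.gsd

    def __post_init__(self) -> None:
        if self.dn_cube.shape[0] != len(self.band_grid):
            raise ValueError("dn_cube band count must equal the band grid length")
        if np.any(self.dsm < self.ground_elevation - 1e-9):
            raise ValueError("dsm must be >= ground elevation everywhere")


def solar_illumination(grid: BandGrid) -> np.ndarray:
    """Smooth solar-like at-canopy irradiance curve (relative units)."""
    lam = grid.centers
    return 0.85 + 0.3 * np.exp(-0.5 * ((lam - 570.0) / 150.0) ** 2)


def soil_spectrum(grid: BandGrid) -> np.ndarray:
    """Bright bare-soil library spectrum: slowly rising with wavelength."""
    lam = grid.centers
    return 0.12 + 0.00025 * (lam - 500.0)


def grass_spectrum(grid: BandGrid) -> np.ndarray:
    """Inter-row grass cover: vegetation-shaped but flatter than vine canopy."""
    lam = grid.centers
    logistic = 1.0 / (1.0 + np.exp(-(lam - 710.0) / 14.0))
    bump = np.exp(-0.5 * ((lam - 550.0) / 15.0) ** 2)
    return 0.06 + (0.30 - 0.06) * logistic + 0.03 * bump


def render_scene(
    traits: pd.DataFrame,
    grid: BandGrid | None = None,
    model: CanopyForwardModel | None = None,
    layout: SceneLayout | None = None,
    seed: int = 0,
    spec: TraitSpec | None = None,
) -> SceneRaster:
    """Render the full scene for a trait table.

    Vines fill row-major positions (west to east row, south to north
    within each row); a table larger than the layout capacity raises
    :class:`LayoutError`.  Deterministic under fixed inputs and seed.
    """
    grid = make_band_grid() if grid is None else grid
    layout = SceneLayout() if layout is None else layout
    model = CanopyForwardModel() if model is None else model

    n_vines = len(traits)
    capacity = layout.n_rows * layout.vines_per_row
    if n_vines > capacity:
        raise LayoutError(f"layout fits {capacity} vines, trait table has {n_vines}")
    n_panels = len(PANEL_REFLECTANCES)
    panels_width = n_panels * layout.panel_size + (n_panels - 1) * layout.panel_size
    if panels_width > layout.width or layout.panel_size > layout.panel_strip:
        raise LayoutError("panel strip cannot hold the five reference panels")

    nx = int(round(layout.width / layout.gsd))
    ny = int(round(layout.height / layout.gsd))
    raster = RasterGrid(ny=ny, nx=nx, gsd=layout.gsd)
    X, Y = raster.pixel_centers()
    B = len(grid)

    # vine canopy spectra; noise-free oracle mode silences the canopy noise too
    eff_model = model
    if not layout.quantize and layout.dn_noise_sd == 0:
        eff_model = replace(model, noise_sd=0.0)
    spectra = canopy_reflectance(traits, grid, eff_model, seed=seed, spec=spec)

    # ---- geometry ----------------------------------------------------
    south_plant = layout.panel_strip + layout.margin
    row_x = layout.margin + np.arange(layout.n_rows) * layout.row_spacing
    vine_rows = np.repeat(np.arange(layout.n_rows), layout.vines_per_row)[:n_vines]
    vine_slots = np.tile(np.arange(layout.vines_per_row), layout.n_rows)[:n_vines]
    vx = row_x[vine_rows]
    vy = south_plant + (vine_slots + 0.5) * layout.vine_spacing
    vine_points = pd.DataFrame(
        {"vine_id": traits["vine_id"].to_numpy(), "x": vx, "y": vy}
    )

    class_mask = np.full((ny, nx), CLASS_CODES["soil"], dtype=np.uint8)
    vine_id_map = np.full((ny, nx), -1, dtype=np.int32)

    # grass strips centered in each inter-row gap
    for i in range(layout.n_rows - 1):
        cx = row_x[i] + layout.row_spacing / 2.0
        sel = (np.abs(X - cx) <= layout.grass_strip_width / 2.0) & (Y >= south_plant) & (
            Y <= south_plant + layout.vines_per_row * layout.vine_spacing
        )
        class_mask[sel] = CLASS_CODES["grass"]

    # canopy strips: west part sunlit canopy, east strip shaded leaves
    half = layout.canopy_width / 2.0
    canopy_sel = np.zeros((ny, nx), dtype=bool)
    shadow_sel = np.zeros((ny, nx), dtype=bool)
    for k in range(n_vines):
        seg = (
            (np.abs(X - vx[k]) <= half)
            & (Y >= vy[k] - layout.vine_spacing / 2.0)
            & (Y < vy[k] + layout.vine_spacing / 2.0)
        )
        shaded = seg & (X > vx[k] + half - layout.shadow_width)
        sunlit = seg & ~shaded
        canopy_sel |= sunlit
        shadow_sel |= shaded
        vine_id_map[seg] = k
    class_mask[canopy_sel] = CLASS_CODES["canopy"]
    class_mask[shadow_sel] = CLASS_CODES["shadow"]

    # reference panels in the southern strip
    panel_specs: list[tuple[Polygon, float]] = []
    px0 = layout.margin
    py = (layout.panel_strip - layout.panel_size) / 2.0
    for rho in PANEL_REFLECTANCES:
        poly = box(px0, py, px0 + layout.panel_size, py + layout.panel_size)
        panel_specs.append((poly, rho))
        px0 += 2 * layout.panel_size
    panel_pix = np.full((ny, nx), -1, dtype=np.int8)
    for i, (poly, _) in enumerate(panel_specs):
        m = raster.mask_for_polygon(poly)
        panel_pix[m] = i
        class_mask[m] = CLASS_CODES["panel"]

    # ---- surfaces ----------------------------------------------------
    ground = np.full((ny, nx), layout.ground_elevation, dtype=float)
    dsm = ground.copy()
    raised = canopy_sel | shadow_sel
    dsm[raised] += layout.canopy_height

    # ---- reflectance truth -------------------------------------------
    refl = np.empty((B, ny, nx), dtype=np.float64)
    refl[:] = soil_spectrum(grid)[:, None, None]
    gsel = class_mask == CLASS_CODES["grass"]
    refl[:, gsel] = grass_spectrum(grid)[:, None]
    for k in range(n_vines):
        vsel = (vine_id_map == k) & canopy_sel
        ssel = (vine_id_map == k) & shadow_sel
        spec_k = spectra.values[k]
        refl[:, vsel] = spec_k[:, None]
        refl[:, ssel] = (spec_k * layout.shade_factor)[:, None]
    for i, (_, rho) in enumerate(panel_specs):
        refl[:, panel_pix == i] = rho

    # ---- DN formation ------------------------------------------------
    illum = np.ones(B) if layout.flat_illumination else solar_illumination(grid)
    gains = illum / layout.dn_full_scale  # radiance per count
    dark = np.full(B, layout.dark_counts)
    radiometry = RadiometricConfig(gains=gains, dark=dark)
    radiance = refl * illum[:, None, None]
    dn = radiance / gains[:, None, None] + dark[:, None, None]
    if layout.dn_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        dn = dn + layout.dn_noise_sd * rng.standard_normal(dn.shape)
    if layout.quantize:
        dn = np.round(dn)
        dn = np.clip(dn, 0.0, None).astype(np.float32)  # integral counts: exact
    else:
        dn = np.clip(dn, 0.0, None).astype(np.float64)  # continuous oracle mode

    rois = [
        ROIPolygon(
            vine_id=int(r.vine_id),
            polygon=box(
                r.x - layout.roi_size / 2.0,
                r.y - layout.roi_size / 2.0,
                r.x + layout.roi_size / 2.0,
                r.y + layout.roi_size / 2.0,
            ),
        )
        for r in vine_points.itertuples()
    ]

    return SceneRaster(
        band_grid=grid,
        raster=raster,
        dn_cube=dn,
        dsm=dsm,
        ground_elevation=ground,
        class_mask=class_mask,
        panel_specs=panel_specs,
        vine_points=vine_points,
        rois=rois,
        radiometry=radiometry,
        reflectance_truth=refl,
        vine_id_map=vine_id_map,
        canopy_spectra=spectra,
        layout=layout,
    )
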