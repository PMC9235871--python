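"""Radiometric calibration: DN → radiance → surface reflectance.

The sensor chain is modelled as ``DN = L / gain + dark (+ noise)`` per
band, inverted here as ``L = gain · (DN − dark)`` using the factory gains
and dark-current counts.  Radiance maps to reflectance with the empirical
line method (ELM): an ordinary least-squares line per band through the
(mean radiance, known reflectance) points of the reference panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .bands import BandGrid
from .rastergrid import RasterGrid

__all__ = [
    "RadiometricConfig",
    "ELMCoefficients",
    "DegenerateFitError",
    "dn_to_radiance",
    "fit_elm",
    "apply_elm",
    "panel_mean_radiances",
]

log = logging.getLogger(__name__)

PANEL_REFLECTANCES = (0.02, 0.09, 0.25, 0.50, 0.88)


class DegenerateFitError(ValueError):
    """ELM cannot be fitted (too few panels or no radiance spread)."""


@dataclass(frozen=True)
class RadiometricConfig:
    """Per-band factory gains (radiance per count) and dark current (counts)."""

    gains: np.ndarray
    dark: np.ndarray
    integration_time_ms: float = 1.0
    dark_in_dn: bool = True  # subtract dark before gain (DN domain, default)

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.gains, dtype=float))
        d = np.atleast_1d(np.asarray(self.dark, dtype=float))
        if g.shape != d.shape:
            raise ValueError("gains and dark must have the same band count")
        if np.any(g <= 0):
            raise ValueError("gains must be positive")
        if np.any(d < 0):
            raise ValueError("dark current must be non-negative")
        if self.integration_time_ms <= 0:
            raise ValueError("integration time must be positive")
        object.__setattr__(self, "gains", g)
        object.__setattr__(self, "dark", d)

    @property
    def n_bands(self) -> int:
        return self.gains.size


def dn_to_radiance(dn_cube: np.ndarray, config: RadiometricConfig) -> np.ndarray:
    """Convert a DN cube (bands first) to radiance.

    Default order subtracts dark current in the DN domain:
    ``L_b = gain_b · (DN_b − dark_b)``; with ``dark_in_dn=False`` the
    subtraction happens after gain scaling (``L = gain·DN − gain·dark``
    differs only when gain varies within a band, so the two orders agree
    for per-band constants — both are exposed because sensor manuals
    state them inconsistently).  Negative radiances (DN below dark) are
    preserved and logged, not clipped.
    """
    dn = np.asarray(dn_cube, dtype=float)
    if dn.shape[0] != config.n_bands:
        raise ValueError(f"cube has {dn.shape[0]} bands, config has {config.n_bands}")
    shape = (config.n_bands,) + (1,) * (dn.ndim - 1)
    g = config.gains.reshape(shape)
    d = config.dark.reshape(shape)
    if config.dark_in_dn:
        rad = g * (dn - d)
    else:
        rad = g * dn - g * d
    n_neg = int(np.sum(rad < 0))
    if n_neg:
        log.warning("dn_to_radiance: %d values below dark current (negative radiance kept)", n_neg)
    return rad


@dataclass(frozen=True)
class ELMCoefficients:
    """Per-band affine map reflectance = slope · radiance + intercept."""

    slope: np.ndarray
    intercept: np.ndarray
    rms: np.ndarray
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.atleast_1d(np.asarray(self.slope, dtype=float))
        i = np.atleast_1d(np.asarray(self.intercept, dtype=float))
        r = np.atleast_1d(np.asarray(self.rms, dtype=float))
        if not (s.shape == i.shape == r.shape):
            raise ValueError("slope, intercept and rms must share one entry per band")
        if not np.all(np.isfinite(s)):
            raise ValueError("slopes must be finite")
        object.__setattr__(self, "slope", s)
        object.__setattr__(self, "intercept", i)
        object.__setattr__(self, "rms", r)

    @property
    def n_bands(self) -> int:
        return self.slope.size

    def to_frame(self) -> pd.DataFrame:
        wl = self.wavelengths if self.wavelengths is not None else np.arange(self.n_bands)
        return pd.DataFrame(
            {
                "band": np.arange(self.n_bands),
                "wavelength_nm": np.asarray(wl, dtype=float),
                "slope": self.slope,
                "intercept": self.intercept,
                "rms": self.rms,
            }
        )


def fit_elm(
    panel_radiances: np.ndarray,
    panel_reflectances: np.ndarray = PANEL_REFLECTANCES,
    grid: BandGrid | None = None,
) -> ELMCoefficients:
    """Fit the empirical line per band over the reference panels.

    ``panel_radiances`` is (n_panels, n_bands); ``panel_reflectances``
    the known fractions.  Requires at least two panels with distinct
    radiances in every band; a band without spread cannot anchor a line
    and raises :class:`DegenerateFitError` naming it.
    """
    L = np.atleast_2d(np.asarray(panel_radiances, dtype=float))
    rho = np.asarray(panel_reflectances, dtype=float)
    if L.shape[0] != rho.size:
        raise ValueError("one radiance row per panel required")
    if rho.size < 2:
        raise DegenerateFitError("need at least 2 panels to fit the empirical line")
    n_bands = L.shape[1]
    spread = L.max(axis=0) - L.min(axis=0)
    bad = np.nonzero(spread <= 0)[0]
    if bad.size:
        raise DegenerateFitError(f"zero radiance spread in band(s) {bad.tolist()}")
    Lm = L.mean(axis=0)
    rm = rho.mean()
    cov = ((L - Lm) * (rho[:, None] - rm)).sum(axis=0)
    var = ((L - Lm) ** 2).sum(axis=0)
    slope = cov / var
    intercept = rm - slope * Lm
    resid = rho[:, None] - (slope * L + intercept)
    rms = np.sqrt((resid**2).mean(axis=0))
    wl = grid.centers if grid is not None else None
    return ELMCoefficients(slope=slope, intercept=intercept, rms=rms, wavelengths=wl)


def apply_elm(
    radiance_cube: np.ndarray, coeffs: ELMCoefficients, clip_policy: str = "none"
) -> np.ndarray:
    """Affine radiance → reflectance per band.

    ``clip_policy``: "none" (default, negative / >1 values preserved for
    downstream filters to judge) or "unit" (clip to [0, 1], logging the
    clipped fraction).
    """
    rad = np.asarray(radiance_cube, dtype=float)
    if rad.shape[0] != coeffs.n_bands:
        raise ValueError(f"cube has {rad.shape[0]} bands, coefficients have {coeffs.n_bands}")
    shape = (coeffs.n_bands,) + (1,) * (rad.ndim - 1)
    refl = coeffs.slope.reshape(shape) * rad + coeffs.intercept.reshape(shape)
    if clip_policy == "unit":
        frac = float(np.mean((refl < 0) | (refl > 1)))
        if frac:
            log.warning("apply_elm: clipped %.3f%% of values to [0, 1]", 100 * frac)
        refl = np.clip(refl, 0.0, 1.0)
    elif clip_policy != "none":
        raise ValueError(f"unknown clip_policy {clip_policy!r}")
    return refl


def panel_mean_radiances(
    radiance_cube: np.ndarray,
    panel_polygons: list[Polygon],
    raster: RasterGrid,
    erode_pixels: int = 1,
) -> np.ndarray:
    """Mean radiance per band over each panel's inner pixels.

    Polygons are eroded by one pixel by default so boundary mixels do
    not bias the panel means (standard ELM practice).
    """
    out = np.empty((len(panel_polygons), radiance_cube.shape[0]))
    for i, poly in enumerate(panel_polygons):
        mask = raster.mask_for_polygon(poly, erode_pixels=erode_pixels)
        if not mask.any():
            mask = raster.mask_for_polygon(poly, erode_pixels=0)
        if not mask.any():
            raise ValueError(f"panel {i} covers no pixel centers")
        out[i] = radiance_cube[:, mask].mean(axis=1)
    return out
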