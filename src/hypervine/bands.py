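"""Sensor wavelength axis.

A frame-based visible/NIR hyperspectral camera records a configurable set of
narrow bands; here the axis is a list of band centers (nm) with a common
full width at half maximum (FWHM).  Every ``R_λ`` lookup in an index formula
resolves against this grid by nearest-center matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BandGrid", "make_band_grid", "nearest_band", "UnresolvableWavelengthError"]


class UnresolvableWavelengthError(ValueError):
    """No band center lies within tolerance of the requested wavelength."""


@dataclass(frozen=True)
class BandGrid:
    """Discrete wavelength axis of the sensor.

    Parameters
    ----------
    centers
        Band-center wavelengths in nm, strictly increasing, within [500, 900].
    fwhm
        Full width at half maximum of each band's spectral response, nm.
    """

    centers: np.ndarray
    fwhm: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("band grid needs at least two centers")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        if centers[0] < 500.0 - 1e-9 or centers[-1] > 900.0 + 1e-9:
            raise ValueError("band centers must lie within [500, 900] nm")
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")

    def __len__(self) -> int:
        return int(self.centers.size)

    @property
    def n_bands(self) -> int:
        return len(self)


def make_band_grid(
    n_bands: int = 50,
    lambda_min: float = 500.0,
    lambda_max: float = 900.0,
    fwhm: float = 8.0,
) -> BandGrid:
    """Equally spaced band grid with inclusive endpoints.

    The default reproduces the sensor configuration used throughout the
    package: 50 bands spanning 500–900 nm, FWHM ≈ 8 nm, i.e. a center
    spacing of 400/49 ≈ 8.16 nm.
    """
    if n_bands < 2:
        raise ValueError(f"n_bands must be >= 2, got {n_bands}")
    if not lambda_min < lambda_max:
        raise ValueError(f"need lambda_min < lambda_max, got {lambda_min} >= {lambda_max}")
    centers = np.linspace(float(lambda_min), float(lambda_max), int(n_bands))
    return BandGrid(centers=centers, fwhm=float(fwhm))


def nearest_band(grid: BandGrid, wavelength: float, tolerance: float | None = None) -> int:
    """Index of the band center nearest ``wavelength``.

    Ties resolve to the lower index.  ``tolerance`` defaults to the grid
    FWHM; a nearest center farther than that raises
    :class:`UnresolvableWavelengthError` (the formula wavelength simply is
    not covered by the sensor configuration).
    """
    tol = grid.fwhm if tolerance is None else float(tolerance)
    if not tol > 0:
        raise ValueError("tolerance must be positive")
    dist = np.abs(grid.centers - float(wavelength))
    idx = int(np.argmin(dist))  # argmin takes the first (lower) index on ties
    if dist[idx] > tol:
        raise UnresolvableWavelengthError(
            f"no band within {tol} nm of {wavelength} nm "
            f"(nearest center {grid.centers[idx]:.2f} nm, |Δ| = {dist[idx]:.2f})"
        )
    return idx
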