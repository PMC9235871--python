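"""Shared container for per-vine spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BandGrid

__all__ = ["SpectralDataset"]


@dataclass
class SpectralDataset:
    """n × B matrix of per-vine mean reflectance spectra.

    ``values[i, b]`` is vine ``vine_id[i]``'s mean reflectance in band
    ``b`` of ``grid``; ``n_pixels`` counts the masked pixels that entered
    each mean (1 for directly simulated spectra).
    """

    vine_id: np.ndarray
    values: np.ndarray
    grid: BandGrid
    n_pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vine_id = np.asarray(self.vine_id)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (vines x bands)")
        if self.values.shape[0] != self.vine_id.size:
            raise ValueError("vine_id length must match number of rows")
        if self.values.shape[1] != len(self.grid):
            raise ValueError(
                f"band count {self.values.shape[1]} does not match grid length {len(self.grid)}"
            )
        if self.n_pixels is None:
            self.n_pixels = np.ones(self.vine_id.size, dtype=int)
        else:
            self.n_pixels = np.asarray(self.n_pixels, dtype=int)
            if np.any(self.n_pixels < 1):
                raise ValueError("each retained vine needs at least one pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready frame: vine_id, n_pixels, R_<wavelength> columns
        (wavelengths rounded to 0.1 nm)."""
        cols = {f"R_{w:.1f}": self.values[:, j] for j, w in enumerate(self.grid.centers)}
        return pd.DataFrame({"vine_id": self.vine_id, "n_pixels": self.n_pixels, **cols})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, grid: BandGrid) -> "SpectralDataset":
        rcols = [c for c in frame.columns if c.startswith("R_")]
        if len(rcols) != len(grid):
            raise ValueError("frame band columns do not match grid")
        npx = frame["n_pixels"].to_numpy() if "n_pixels" in frame else None
        return cls(
            vine_id=frame["vine_id"].to_numpy(),
            values=frame[rcols].to_numpy(dtype=float),
            grid=grid,
            n_pixels=npx,
        )
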