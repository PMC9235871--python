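"""Trait-linked canopy reflectance forward model.

Real vine canopies were imaged in the original campaign; here a minimal
parametric stand-in generates spectra with known ground truth so the whole
retrieval chain is testable.  A canopy spectrum is

    R(λ) = vis + (nir − vis) · logistic((λ − λ_re) / w) + g · exp(−(λ−550)²/(2·15²))

a visible baseline rising through a logistic red edge to an NIR plateau,
plus a Gaussian green-reflectance bump at 550 nm.  Traits drive the
parameters: the NIR plateau rises with total leaf area and falls with water
stress (more negative Ψpd), the red-edge inflection λ_re shifts to shorter
wavelengths under stress, and the green bump tracks a vigor composite.
Couplings are linear in the trait's deviation from its published mean, so
with zero noise every coupled trait is an exact monotone function of some
band's reflectance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BandGrid
from .spectra import SpectralDataset
from .traits import TraitSpec, table2_spec

__all__ = ["CanopyForwardModel", "canopy_reflectance", "TraitDomainError"]

_GREEN_CENTER = 550.0
_GREEN_WIDTH = 15.0
_CLIP = 1e-4  # outputs kept strictly inside (0, 1)


class TraitDomainError(ValueError):
    """Trait values fall outside the declared specification bounds."""


@dataclass(frozen=True)
class CanopyForwardModel:
    """Parameters of the canopy spectrum generator.

    Reflectance parameters are fractions in (0, 1); ``red_edge_center`` is
    the unstressed inflection wavelength (nm, must lie in the 690–740 nm
    red-edge region); coupling coefficients are per trait-unit
    (reflectance/MPa, reflectance/m², nm/MPa, ...).
    """

    vis_baseline: float = 0.05
    nir_plateau_base: float = 0.45
    green_bump_amplitude: float = 0.04
    red_edge_center: float = 715.0
    red_edge_width: float = 12.0
    nir_per_tla: float = 0.05        # reflectance per m2 leaf area deviation
    nir_per_psi: float = 0.30        # reflectance per MPa of Ψpd deviation
    redshift_per_psi: float = 25.0   # nm per MPa of Ψpd deviation
    green_per_vigor: float = 0.015   # reflectance per unit vigor z-score
    noise_sd: float = 0.01           # multiplicative lognormal sd

    def __post_init__(self) -> None:
        for name in ("vis_baseline", "nir_plateau_base", "green_bump_amplitude"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 690.0 < self.red_edge_center < 740.0:
            raise ValueError("red_edge_center must lie in (690, 740) nm")
        if not self.red_edge_width > 0:
            raise ValueError("red_edge_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_couplings_off(self) -> "CanopyForwardModel":
        from dataclasses import replace

        return replace(self, nir_per_tla=0.0, nir_per_psi=0.0,
                       redshift_per_psi=0.0, green_per_vigor=0.0)


def _vigor_composite(traits: pd.DataFrame, spec: TraitSpec) -> np.ndarray:
    """Standardised mean of the canopy-growth traits available in the table."""
    parts = []
    for name in ("tla", "lla", "pwt"):
        if name in traits.columns:
            t = spec.trait(name)
            parts.append((traits[name].to_numpy(dtype=float) - t.mean) / max(t.sd, 1e-12))
    if not parts:
        return np.zeros(len(traits))
    return np.mean(parts, axis=0)


def canopy_reflectance(
    traits: pd.DataFrame,
    grid: BandGrid,
    model: CanopyForwardModel | None = None,
    seed: int = 0,
    spec: TraitSpec | None = None,
) -> SpectralDataset:
    """Per-vine canopy spectra from the forward model.

    ``traits`` is a trait table with a ``vine_id`` column; ``spec``
    (default: the published calibration) provides the trait means the
    couplings pivot on and the bounds the inputs are validated against.
    Deterministic under a fixed ``seed``.
    """
    if len(traits) == 0:
        raise ValueError("trait table is empty")
    model = CanopyForwardModel() if model is None else model
    spec = table2_spec() if spec is None else spec

    for t in spec.traits:
        if t.name in traits.columns:
            x = traits[t.name].to_numpy(dtype=float)
            if np.any(x < t.vmin - 1e-9) or np.any(x > t.vmax + 1e-9):
                raise TraitDomainError(
                    f"trait '{t.name}' has values outside [{t.vmin}, {t.vmax}]"
                )

    n = len(traits)
    lam = grid.centers[None, :]  # (1, B)

    def dev(name: str) -> np.ndarray:
        if name in traits.columns:
            return traits[name].to_numpy(dtype=float) - spec.trait(name).mean
        return np.zeros(n)

    nir = model.nir_plateau_base + model.nir_per_tla * dev("tla") + model.nir_per_psi * dev("psi_pd")
    lam_re = model.red_edge_center + model.redshift_per_psi * dev("psi_pd")
    green = model.green_bump_amplitude + model.green_per_vigor * _vigor_composite(traits, spec)

    logistic = 1.0 / (1.0 + np.exp(-(lam - lam_re[:, None]) / model.red_edge_width))
    bump = np.exp(-0.5 * ((lam - _GREEN_CENTER) / _GREEN_WIDTH) ** 2)
    r = model.vis_baseline + (nir[:, None] - model.vis_baseline) * logistic + green[:, None] * bump

    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r * np.exp(model.noise_sd * rng.standard_normal(r.shape))

    r = np.clip(r, _CLIP, 1.0 - _CLIP)
    return SpectralDataset(vine_id=traits["vine_id"].to_numpy(), values=r, grid=grid)
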