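"""End-to-end pipeline: simulate → calibrate → segment → extract → indices
→ univariate → PLS/iPLS → reports.

Every stage reads and writes plain files in a run directory, so the chain
can be re-entered at any point (the CLI subcommands map one-to-one onto
the ``stage_*`` functions).  A manifest records the configuration hash,
seeds and per-stage counts; re-running the same configuration reproduces
byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point

from . import io as hio
from .bands import make_band_grid
from .canopy import CanopyForwardModel
from .chemometrics import build_model_report, univariate_table
from .indices import compute_all, registry_frame
from .radiometry import (
    PANEL_REFLECTANCES,
    RadiometricConfig,
    apply_elm,
    dn_to_radiance,
    fit_elm,
    panel_mean_radiances,
)
from .scene import CLASS_CODES, SceneLayout, render_scene
from .segmentation import ROIPolygon, SegmentationConfig, canopy_mask, compute_chm, extract_roi_spectra
from .spectra import SpectralDataset
from .traits import sample_traits, table2_spec

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """Flat key-value pipeline configuration (see ``data/demo.yaml``)."""

    seed: int = 1
    n_vines: int = 60
    ecophys_subset: int = 30      # vines carrying water-potential readings
    n_rows: int = 6
    vines_per_row: int = 10
    gsd: float = 0.05
    noise_free: bool = False
    canopy_noise_sd: float = 0.01
    dn_noise_sd: float = 20.0
    aggregation: str = "index-mean"
    dhvi_mode: str = "window"
    clip_policy: str = "none"
    height_threshold_m: float = 0.5
    shadow_threshold: float = 0.15
    cv_k: int = 3
    lv_max: int = 10
    ipls_widths: tuple[int, ...] = (10, 5)
    centering: str = "fold"

    def __post_init__(self) -> None:
        if self.n_vines < 1 or self.ecophys_subset > self.n_vines:
            raise ConfigError("need 1 <= ecophys_subset <= n_vines")
        if self.n_rows * self.vines_per_row < self.n_vines:
            raise ConfigError("layout capacity below n_vines")
        if self.aggregation not in ("index-mean", "spectrum-mean"):
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        object.__setattr__(self, "ipls_widths", tuple(int(w) for w in self.ipls_widths))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**raw)
    except TypeError as e:
        raise ConfigError(str(e)) from e


def _layout(cfg: PipelineConfig) -> SceneLayout:
    layout = SceneLayout(
        n_rows=cfg.n_rows,
        vines_per_row=cfg.vines_per_row,
        gsd=cfg.gsd,
        dn_noise_sd=cfg.dn_noise_sd,
    )
    return layout.noise_free() if cfg.noise_free else layout


def _model(cfg: PipelineConfig) -> CanopyForwardModel:
    return CanopyForwardModel(noise_sd=0.0 if cfg.noise_free else cfg.canopy_noise_sd)


# ------------------------------------------------------------------ stages


def stage_simulate(cfg: PipelineConfig, rundir: Path) -> dict:
    """Traits + rendered scene; writes rasters, vectors and the trait CSV."""
    spec = table2_spec()
    traits = sample_traits(spec, cfg.n_vines, cfg.seed)
    # water potentials are measured on a seeded random subset of the cohort
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99]))
    subset = np.sort(rng.choice(cfg.n_vines, size=cfg.ecophys_subset, replace=False))
    measured = traits.copy()
    unmeasured = ~measured.index.isin(subset)
    measured.loc[unmeasured, ["psi_pd", "psi_md"]] = np.nan
    measured.to_csv(rundir / "traits.csv", index=False)

    scene = render_scene(traits, make_band_grid(), _model(cfg), _layout(cfg), seed=cfg.seed)
    hio.write_raster(rundir / "dn_cube.tif", scene.dn_cube, scene.raster,
                     wavelengths=scene.band_grid.centers, description="DN hypercube")
    hio.write_raster(rundir / "dsm.tif", scene.dsm, scene.raster, description="surface model (m)")
    hio.write_raster(rundir / "class_truth.tif", scene.class_mask, scene.raster,
                     description=f"truth classes {CLASS_CODES}")
    hio.write_geojson(rundir / "panels.geojson",
                      [(p, {"reflectance": r}) for p, r in scene.panel_specs])
    hio.write_geojson(rundir / "vines.geojson",
                      [(Point(r.x, r.y), {"vine_id": int(r.vine_id)})
                       for r in scene.vine_points.itertuples()])
    hio.write_geojson(rundir / "rois.geojson",
                      [(r.polygon, {"vine_id": r.vine_id}) for r in scene.rois])
    pd.DataFrame({"band": range(len(scene.band_grid)),
                  "wavelength_nm": scene.band_grid.centers,
                  "gain": scene.radiometry.gains,
                  "dark": scene.radiometry.dark}).to_csv(rundir / "radiometry.csv", index=False)
    scene.canopy_spectra.to_frame().to_csv(rundir / "canopy_truth.csv", index=False)
    return {"n_vines": int(cfg.n_vines), "n_bands": len(scene.band_grid),
            "n_panels": len(scene.panel_specs),
            "raster_shape": list(scene.dn_cube.shape)}


def stage_calibrate(cfg: PipelineConfig, rundir: Path) -> dict:
    """DN → radiance → reflectance via the panel-fitted empirical line."""
    dn, raster, meta = hio.read_raster(rundir / "dn_cube.tif")
    rad_tab = pd.read_csv(rundir / "radiometry.csv")
    config = RadiometricConfig(gains=rad_tab["gain"].to_numpy(),
                               dark=rad_tab["dark"].to_numpy())
    grid = make_band_grid(n_bands=dn.shape[0])
    radiance = dn_to_radiance(dn, config)
    panels = hio.read_geojson(rundir / "panels.geojson")
    pm = panel_mean_radiances(radiance, [g for g, _ in panels], raster)
    rho = np.array([p["reflectance"] for _, p in panels])
    coeffs = fit_elm(pm, rho, grid)
    refl = apply_elm(radiance, coeffs, clip_policy=cfg.clip_policy)
    hio.write_raster(rundir / "reflectance.tif", refl.astype(np.float32), raster,
                     wavelengths=grid.centers, description="ELM reflectance")
    coeffs.to_frame().to_csv(rundir / "elm_coefficients.csv", index=False)
    recovered = coeffs.slope * pm + coeffs.intercept
    err = np.abs(recovered - rho[:, None]).max()
    pd.DataFrame({"panel_reflectance": rho,
                  "max_abs_error": np.abs(recovered - rho[:, None]).max(axis=1)}
                 ).to_csv(rundir / "panel_recovery.csv", index=False)
    return {"panel_max_abs_error": float(err),
            "n_panels": len(panels), "clip_policy": cfg.clip_policy}


def stage_segment(cfg: PipelineConfig, rundir: Path) -> dict:
    """Canopy height model + height/shadow threshold mask."""
    dsm, raster, _ = hio.read_raster(rundir / "dsm.tif")
    refl, _, meta = hio.read_raster(rundir / "reflectance.tif")
    grid = make_band_grid(n_bands=refl.shape[0])
    seg = SegmentationConfig(height_threshold_m=cfg.height_threshold_m,
                             shadow_threshold=cfg.shadow_threshold)
    chm = compute_chm(dsm, seg, raster.gsd)
    mask = canopy_mask(chm, refl, seg, grid)
    hio.write_raster(rundir / "chm.tif", chm.astype(np.float32), raster, description="CHM (m)")
    hio.write_raster(rundir / "canopy_mask.tif", mask.astype(np.uint8), raster,
                     description="canopy mask")
    return {"canopy_pixels": int(mask.sum()),
            "canopy_fraction": float(mask.mean())}


def stage_extract(cfg: PipelineConfig, rundir: Path) -> dict:
    """Per-vine mean spectra over masked ROI pixels → spectral dataset CSV."""
    refl, raster, _ = hio.read_raster(rundir / "reflectance.tif")
    mask, _, _ = hio.read_raster(rundir / "canopy_mask.tif")
    grid = make_band_grid(n_bands=refl.shape[0])
    rois = [ROIPolygon(vine_id=int(p["vine_id"]), polygon=g)
            for g, p in hio.read_geojson(rundir / "rois.geojson")]
    ds = extract_roi_spectra(refl, mask.astype(bool), rois, raster, grid)
    ds.to_frame().to_csv(rundir / "spectral_dataset.csv", index=False)
    return {"n_vines_retained": int(ds.shape[0]), "n_bands": int(ds.shape[1]),
            "min_pixels": int(ds.n_pixels.min()), "dataset_shape": list(ds.shape)}


def stage_indices(cfg: PipelineConfig, rundir: Path) -> dict:
    """All registered narrowband indices per vine."""
    grid = make_band_grid()
    if cfg.aggregation == "index-mean":
        refl, raster, _ = hio.read_raster(rundir / "reflectance.tif")
        mask, _, _ = hio.read_raster(rundir / "canopy_mask.tif")
        rois = [ROIPolygon(vine_id=int(p["vine_id"]), polygon=g)
                for g, p in hio.read_geojson(rundir / "rois.geojson")]
        vi = compute_all(grid=grid, cube=refl, mask=mask.astype(bool), rois=rois,
                         raster=raster, aggregation="index-mean", dhvi_mode=cfg.dhvi_mode)
    else:
        ds = SpectralDataset.from_frame(pd.read_csv(rundir / "spectral_dataset.csv"), grid)
        vi = compute_all(dataset=ds, grid=grid, aggregation="spectrum-mean",
                         dhvi_mode=cfg.dhvi_mode)
    vi.to_csv(rundir / "vegetation_indices.csv", index=False)
    registry_frame().to_csv(rundir / "index_registry.csv", index=False)
    return {"n_indices": int(vi.shape[1] - 1), "n_vines": int(vi.shape[0]),
            "aggregation": cfg.aggregation}


def stage_univariate(cfg: PipelineConfig, rundir: Path) -> dict:
    """Index-vs-trait linear regression matrix with significance classes."""
    vi = pd.read_csv(rundir / "vegetation_indices.csv")
    traits = pd.read_csv(rundir / "traits.csv")
    table = univariate_table(vi, traits)
    table.to_csv(rundir / "univariate_long.csv", index=False)
    r2 = table.pivot(index="index", columns="trait", values="r_squared")
    sig = table.pivot(index="index", columns="trait", values="sig_class")
    r2.to_csv(rundir / "univariate_r2_matrix.csv")
    sig.to_csv(rundir / "univariate_sig_matrix.csv")
    return {"n_cells": int(len(table)),
            "n_significant": int((table["p_value"] < 0.01).sum())}


def stage_models(cfg: PipelineConfig, rundir: Path) -> dict:
    """Full-spectrum PLS and forward iPLS per trait → model report CSV."""
    grid = make_band_grid()
    ds = SpectralDataset.from_frame(pd.read_csv(rundir / "spectral_dataset.csv"), grid)
    traits = pd.read_csv(rundir / "traits.csv")
    report = build_model_report(ds, traits.drop(columns=[], errors="ignore"),
                                lv_max=cfg.lv_max, k=cfg.cv_k, seed=cfg.seed,
                                widths=cfg.ipls_widths, centering=cfg.centering)
    report.to_csv(rundir / "model_report.csv", index=False)
    sizes = report.groupby("y")["n_samples"].first().to_dict()
    for t, n in sizes.items():
        log.info("PLS design for %s: {%d x %d}", t, n, ds.shape[1])
    return {"n_rows": int(len(report)), "n_traits": int(report["y"].nunique()),
            "design_sizes": {t: [int(n), int(ds.shape[1])] for t, n in sizes.items()}}


_STAGES = [
    ("simulate", stage_simulate),
    ("calibrate", stage_calibrate),
    ("segment", stage_segment),
    ("extract", stage_extract),
    ("indices", stage_indices),
    ("univariate", stage_univariate),
    ("models", stage_models),
]


def run_pipeline(cfg: PipelineConfig, rundir: str | Path) -> dict:
    """Execute every stage in order and write ``manifest.json``.

    Any stage failure aborts with the stage name attached; the manifest
    records the configuration hash, the seed, and each stage's counts.
    """
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "config_hash": cfg.config_hash(),
                      "seed": cfg.seed, "stages": {}}
    for name, fn in _STAGES:
        log.info("stage %s ...", name)
        try:
            manifest["stages"][name] = fn(cfg, rundir)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
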