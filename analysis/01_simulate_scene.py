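"""Simulate the study vineyard: trait cohort + rendered hyperspectral scene.

Draws 60 vines from the trait generator calibrated to the published field
summaries (water potentials on a 30-vine subset), renders the block as a
50-band DN hypercube with DSM, truth masks and the five reference panels,
and writes everything to results/vineyard_run/.
"""

import logging
from pathlib import Path

import pandas as pd

from hypervine.pipeline import PipelineConfig, stage_simulate

RUNDIR = Path(__file__).resolve().parents[1] / "results" / "vineyard_run"

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
RUNDIR.mkdir(parents=True, exist_ok=True)

cfg = PipelineConfig()  # the demo study conditions
info = stage_simulate(cfg, RUNDIR)

traits = pd.read_csv(RUNDIR / "traits.csv")
print(f"simulated {info['n_vines']} vines, {info['n_bands']} bands, "
      f"{info['n_panels']} panels; raster {info['raster_shape']}")
print(f"water potentials measured on {traits['psi_pd'].notna().sum()} vines")
print(traits.describe().loc[["mean", "min", "max"]].T.round(3).to_string())
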