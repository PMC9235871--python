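"""Narrowband vegetation indices per vine.

Evaluates every registered index per masked canopy pixel and averages
within each vine's polygon (the study's aggregation), writing the
per-vine index table and the formula registry for audit.
"""

import logging
from pathlib import Path

import pandas as pd

from hypervine.pipeline import PipelineConfig, stage_indices

RUNDIR = Path(__file__).resolve().parents[1] / "results" / "vineyard_run"

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
info = stage_indices(PipelineConfig(), RUNDIR)

vi = pd.read_csv(RUNDIR / "vegetation_indices.csv")
print(f"{info['n_indices']} indices for {info['n_vines']} vines "
      f"({info['aggregation']} aggregation)")
print(vi[["NDVI1", "RVI", "SR680", "REP", "maxLARE"]].describe()
      .loc[["mean", "min", "max"]].round(3).to_string())
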