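"""Multivariate calibration: full-spectrum PLS and forward iPLS.

For every trait, fits a mean-centered PLS model on the {n x 50} spectral
dataset with 3-deletion-group cross-validation (LVs chosen by minimum
RMSECV), plus forward interval-PLS at interval widths 10 and 5.  The best
row per trait (minimum RMSECV, ties broken by R2 CV then variable count)
is flagged.
"""

import logging
from pathlib import Path

import pandas as pd

from hypervine.pipeline import PipelineConfig, stage_models

RUNDIR = Path(__file__).resolve().parents[1] / "results" / "vineyard_run"

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
info = stage_models(PipelineConfig(), RUNDIR)

report = pd.read_csv(RUNDIR / "model_report.csv")
print(f"{info['n_rows']} model rows over {info['n_traits']} traits")
best = report[report.best].copy()
cols = ["y", "method", "interval_size", "selected_bands", "n_lv",
        "rmsec", "rmsecv", "r2_cal", "r2_cv"]
print("best model per trait:")
print(best[cols].round(3).to_string(index=False))
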