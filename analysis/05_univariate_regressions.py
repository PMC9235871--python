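"""Univariate index-trait regressions.

Regresses every vine trait on every narrowband index (pairing by vine;
water potentials use their 30-vine subset) and reports the R-squared
matrix with the four-step significance ladder.
"""

import logging
from pathlib import Path

import pandas as pd

from hypervine.pipeline import PipelineConfig, stage_univariate

RUNDIR = Path(__file__).resolve().parents[1] / "results" / "vineyard_run"

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
info = stage_univariate(PipelineConfig(), RUNDIR)

long = pd.read_csv(RUNDIR / "univariate_long.csv")
print(f"{info['n_cells']} index-trait cells, "
      f"{info['n_significant']} significant at p < 0.01")
best = long.sort_values("r_squared", ascending=False).head(8)
print("strongest relationships:")
print(best[["index", "trait", "r_squared", "sig_class", "n"]]
      .round(3).to_string(index=False))
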