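#!/usr/bin/env python
"""Clinical cross-validation on the simulated paired samples: estimate the
blood-cell-to-plasma partition coefficient per analyte, then check
DBS-vs-plasma agreement by weighted Deming regression and Bland-Altman, before
and after partition-based conversion.

Reads results/sim/paired.csv; writes deming.csv, bland_altman.csv,
partition_fit.csv, calculated_plasma.csv and the four-panel figures under
results/comparison/.
"""

import argparse
from pathlib import Path

import pandas as pd

from dbstdm import Analyte, compare_dbs_plasma
from dbstdm.io import read_paired_table
from dbstdm.pipeline import stage_compare
from dbstdm.plots import comparison_figure

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--in-dir", type=Path, default=Path("results/sim"))
parser.add_argument("--out-dir", type=Path, default=Path("results/comparison"))
args = parser.parse_args()

paths = stage_compare(args.in_dir / "paired.csv", args.out_dir, k_source="fit")

part = pd.read_csv(paths["partition_fit"])
for row in part.itertuples(index=False):
    print(f"K_BC/PL [{row.analyte}] = {row.k_bcpl:.3f} "
          f"(95% CI {row.ci_low:.3f}-{row.ci_high:.3f}, n={row.n})")
dem = pd.read_csv(paths["deming"])
for row in dem[dem.panel == "converted_vs_plasma"].itertuples(index=False):
    covers = row.slope_ci_low <= 1.0 <= row.slope_ci_high
    print(f"converted-vs-measured Deming slope [{row.analyte}] = {row.slope:.3f} "
          f"(CI {row.slope_ci_low:.3f}-{row.slope_ci_high:.3f}; "
          f"{'covers' if covers else 'misses'} identity)")

records = read_paired_table(args.in_dir / "paired.csv")
for analyte in Analyte:
    rep = compare_dbs_plasma(records, analyte, k_source="fit")
    fig = args.out_dir / f"comparison_{analyte.value.lower()}.png"
    comparison_figure(rep, fig)
    print(f"wrote {fig}")
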