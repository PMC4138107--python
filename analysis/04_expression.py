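#!/usr/bin/env python
"""Relative expression after a blood meal, and egg-laying statistics.

Quantifies each target gene against the rp49 reference and the sucrose-fed
calibrator with the efficiency-corrected ΔΔCt ratio, then compares
egg-laying (eggs per female per cage) between treatments with the
pooled-variance t-test (two groups) or one-way ANOVA (more).
"""

import argparse
from pathlib import Path

import pandas as pd

from aedes_ptp.expression import (
    eggs_per_female_table,
    expression_table,
    one_way_anova,
    read_ct_table,
    two_sample_t,
)

parser = argparse.ArgumentParser()
parser.add_argument("--ct", type=Path, default=Path("results/simulated/ct.csv"))
parser.add_argument("--cages", type=Path,
                    default=Path("results/simulated/cages.csv"))
parser.add_argument("--calibrator", default="sucrose_0h")
parser.add_argument("--out", type=Path, default=Path("results/expression"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

ct = read_ct_table(args.ct)
ratios = expression_table(ct, args.calibrator)
ratios.to_csv(args.out / "ratios.csv", index=False)
print("relative expression (vs rp49, calibrator =", args.calibrator + "):")
print(ratios.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

cages = eggs_per_female_table(pd.read_csv(args.cages))
cages.to_csv(args.out / "eggs_per_female.csv", index=False)
groups = {t: g.eggs_per_female.to_numpy() for t, g in cages.groupby("treatment")}
means = {t: g.mean() for t, g in groups.items()}
print("\neggs per female (cage means):",
      ", ".join(f"{t}={m:.1f}" for t, m in means.items()))
vals = list(groups.values())
if len(vals) == 2:
    t, p = two_sample_t(vals[0], vals[1])
    print(f"Student's t-test: t = {t:.3f}, p = {p:.4g}")
else:
    f, p = one_way_anova(*vals)
    print(f"one-way ANOVA: F = {f:.3f}, p = {p:.4g}")
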