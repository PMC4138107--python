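#!/usr/bin/env python
"""Generate every input the downstream analyses need, with ground truth.

Emits, under results/simulated/:
  * the ten-protein repertoire fixture proteome (planted motif strings),
  * a 20-protein random synthetic proteome,
  * an 8-taxon sequence family evolved on a recorded tree,
  * a qPCR Ct table for a blood-meal time course (known fold changes),
  * an egg-count cage table for control vs silenced females.
"""

import argparse
from pathlib import Path

from aedes_ptp.synth import (
    make_cage_table,
    make_ct_table,
    make_family,
    make_proteome,
    save_family,
    save_proteome,
    table1_proteome,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/simulated"))
args = parser.parse_args()
out = args.out
out.mkdir(parents=True, exist_ok=True)

records, truth = table1_proteome(seed=args.seed)
save_proteome(records, truth, out, stem="table1_fixture")
print(f"repertoire fixture: {len(records)} proteins -> {out}/table1_fixture.fasta")

records, truth = make_proteome(20, seed=args.seed)
save_proteome(records, truth, out, stem="random_proteome")
n_dom = sum(len(v) for v in truth.planted_domains.values())
print(f"random proteome: 20 proteins, {n_dom} planted domains")

leaves, truth = make_family(taxa=8, seed=args.seed)
save_family(leaves, truth, out, stem="family")
print(f"sequence family: 8 taxa, truth tree {truth.family_tree}")

ct, truth = make_ct_table(
    {"AAEL001919": {"blood_24h": 2.0, "blood_48h": 4.0, "blood_72h": 1.5},
     "Vg": {"blood_24h": 8.0, "blood_48h": 16.0, "blood_72h": 4.0}},
    calibrator="sucrose_0h", noise_sd=0.2, n_replicates=3, seed=args.seed)
ct.to_csv(out / "ct.csv", index=False)
truth.to_json(out / "ct.truth.json")
print(f"qPCR table: {len(ct)} wells, calibrator sucrose_0h")

cages, truth = make_cage_table({"control": 60.0, "ds1919": 42.0},
                               n_cages=6, seed=args.seed)
cages.to_csv(out / "cages.csv", index=False)
truth.to_json(out / "cages.truth.json")
print(f"cage table: {len(cages)} cages (true means 60 vs 42 eggs/female)")
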