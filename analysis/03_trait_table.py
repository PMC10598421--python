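#!/usr/bin/env python
"""Assemble the species-level trait table.

Spination index (sum of front-leg spine lengths / sum of front-leg segment
lengths) and relative leg length per specimen, averaged per species, joined
with the species sprint speeds from step 02 and the ecological codings
(web builder, cribellate silk, ground dwelling). Species absent from the
tree are dropped with a report.

Run after 02: python analysis/03_trait_table.py
"""

import argparse
from pathlib import Path

import pandas as pd

from marronoid import morpho, treeio

ap = argparse.ArgumentParser()
ap.add_argument("--data-dir", type=Path, default=Path("scratch/study_data"))
ap.add_argument("--out-dir", type=Path, default=Path("results"))
args = ap.parse_args()

records = morpho.records_from_long(pd.read_csv(args.data_dir / "morphometrics.csv"))
speeds = pd.read_csv(args.out_dir / "species_speeds.csv")
ecology = pd.read_csv(args.data_dir / "ecology.csv")
tree = treeio.read_newick((args.data_dir / "tree.nwk").read_text())

tab, dropped = morpho.species_trait_table(records, speeds, ecology,
                                          tree.tip_labels)
tab.to_csv(args.out_dir / "trait_table.csv", index=False)

print(f"{len(tab)} species in the trait table")
if dropped:
    print("dropped (no tip in tree):", ", ".join(dropped))
print(f"mean spination index {tab['spination'].mean():.3f}, "
      f"mean sprint {tab['sprint_rel'].mean():.1f} bl/s")
print(f"-> {args.out_dir / 'trait_table.csv'}")
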