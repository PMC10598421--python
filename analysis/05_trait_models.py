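#!/usr/bin/env python
"""Mode of continuous-trait evolution: BM / OU / EB / Pagel's lambda.

Fits the four models to species sprint speed (bl/s) and spination index
and ranks them by AICc weight; the winning transformation feeds the
phylogenetic regressions in step 06 (lambda for speed, OU for spination
in the empirical study).

Run after 03: python analysis/05_trait_models.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from marronoid import contmodels, treeio

ap = argparse.ArgumentParser()
ap.add_argument("--data-dir", type=Path, default=Path("scratch/study_data"))
ap.add_argument("--out-dir", type=Path, default=Path("results"))
args = ap.parse_args()

tree0 = treeio.read_newick((args.data_dir / "tree.nwk").read_text())
traits = pd.read_csv(args.out_dir / "trait_table.csv").set_index("species")

tabs = []
for trait in ("sprint_rel", "spination"):
    keep = [s for s in tree0.tip_labels
            if s in traits.index and np.isfinite(traits.loc[s, trait])]
    tree = tree0.prune_to(keep)
    vals = {s: float(traits.loc[s, trait]) for s in keep}
    fits = contmodels.fit_all(tree, vals)
    tab = contmodels.model_table(fits)
    tab.insert(0, "trait", trait)
    tabs.append(tab)
    best = tab.iloc[0]
    print(f"{trait}: best model {best['model']} "
          f"(AICc weight {best['weight']:.2f}, n={len(keep)})")

pd.concat(tabs, ignore_index=True).to_csv(args.out_dir / "cont_models.csv",
                                          index=False)
print(f"-> {args.out_dir / 'cont_models.csv'}")
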