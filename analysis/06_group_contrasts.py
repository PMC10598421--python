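#!/usr/bin/env python
"""Do web builders run slower or carry fewer capture spines?

Phylogenetic linear regressions of sprint speed (lambda residuals) and
spination index (OU residuals) on each ecological contrast — web vs
cursorial, cribellate vs ecribellate, ground vs above-ground — plus raw
group mean-difference effect sizes with 5000-replicate bootstrap CIs.

Run after 03: python analysis/06_group_contrasts.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from marronoid import effects, pgls, treeio

ap = argparse.ArgumentParser()
ap.add_argument("--data-dir", type=Path, default=Path("scratch/study_data"))
ap.add_argument("--out-dir", type=Path, default=Path("results"))
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("-B", "--replicates", type=int, default=5000)
args = ap.parse_args()

tree0 = treeio.read_newick((args.data_dir / "tree.nwk").read_text())
traits = pd.read_csv(args.out_dir / "trait_table.csv")
ti = traits.set_index("species")

method_for = {"sprint_rel": "lambda", "spination": "ou"}
rows, eff_rows = [], []
for trait, method in method_for.items():
    keep = [s for s in tree0.tip_labels
            if s in ti.index and np.isfinite(ti.loc[s, trait])]
    tree = tree0.prune_to(keep)
    yv = {s: float(ti.loc[s, trait]) for s in keep}
    for pred in ("web", "cribellar", "ground"):
        xv = {s: float(ti.loc[s, pred]) for s in keep}
        try:
            fit = pgls.phylo_lm(tree, yv, xv, method=method, names=[pred])
        except ValueError as exc:
            print(f"  {trait} ~ {pred}: skipped ({exc})")
            continue
        rep = pgls.group_contrast_report(fit, pred)
        rows.append({"trait": trait, **rep})
        sub = traits.dropna(subset=[trait, pred])
        res = effects.bootstrap_ci(sub[trait].to_numpy(),
                                   sub[pred].to_numpy(),
                                   B=args.replicates, seed=args.seed)
        eff_rows.append({"trait": trait, "predictor": pred,
                         "mean_diff": res.estimate, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "B": res.B})
        print(f"{trait} ~ {pred} ({rep['method']}): "
              f"b = {rep['estimate']:+.3f}, p = {rep['p']:.3f}; "
              f"effect {res.estimate:+.3f} "
              f"(95% CI {res.ci_low:+.3f}, {res.ci_high:+.3f})")

pd.DataFrame(rows).to_csv(args.out_dir / "pgls_contrasts.csv", index=False)
pd.DataFrame(eff_rows).to_csv(args.out_dir / "effect_sizes.csv", index=False)
print(f"-> {args.out_dir / 'pgls_contrasts.csv'}, "
      f"{args.out_dir / 'effect_sizes.csv'}")
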