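#!/usr/bin/env python
"""Evolution of web-building: Mk model comparison and stochastic maps.

Fits equal-rates (ER), all-rates-different (ARD) and Dollo-constrained
(no web re-gain) 2-state Markov models to the web codings, compares them
by AICc weight, then samples stochastic character maps under each fitted
model and counts web losses (1 -> 0) and gains (0 -> 1).

Run after 03: python analysis/04_web_evolution.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from marronoid import mk, treeio

ap = argparse.ArgumentParser()
ap.add_argument("--data-dir", type=Path, default=Path("scratch/study_data"))
ap.add_argument("--out-dir", type=Path, default=Path("results"))
ap.add_argument("--n-maps", type=int, default=500)
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

tree = treeio.read_newick((args.data_dir / "tree.nwk").read_text())
traits = pd.read_csv(args.out_dir / "trait_table.csv").set_index("species")
tree = tree.prune_to([s for s in tree.tip_labels if s in traits.index])
tips = {s: int(traits.loc[s, "web"]) for s in tree.tip_labels}

fits = [mk.fit_mk(tree, tips, c, seed=args.seed) for c in ("ER", "ARD", "DOLLO")]
rows, counts = [], []
for fit, w in zip(fits, mk.aicc_weights(fits)):
    fit.weight = float(w)
    rows.append({"model": fit.model.constraint, "q_gain": fit.model.q01,
                 "q_loss": fit.model.q10, "logLik": fit.loglik,
                 "AICc": fit.aicc, "weight": fit.weight})
    maps = mk.sample_maps(tree, tips, fit.model, n_maps=args.n_maps,
                          seed=args.seed)
    counts.append({"model": fit.model.constraint,
                   **mk.summarize_maps(maps)})

pd.DataFrame(rows).to_csv(args.out_dir / "mk_fits.csv", index=False)
pd.DataFrame(counts).to_csv(args.out_dir / "simmap_counts.csv", index=False)

for r, c in zip(rows, counts):
    print(f"{r['model']:6s} AICc {r['AICc']:8.2f} (w={r['weight']:.2f}): "
          f"mean {c['mean_losses']:.1f} losses, {c['mean_gains']:.1f} gains "
          f"over {args.n_maps} maps")
print(f"-> {args.out_dir / 'mk_fits.csv'}, {args.out_dir / 'simmap_counts.csv'}")
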