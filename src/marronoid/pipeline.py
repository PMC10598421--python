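"""End-to-end orchestration: tracking data -> trait table -> comparative
results, in the order the study runs them.

Stages (each can be toggled off when its output is supplied precomputed):

1. kinematics — per-trial sprint speeds from trajectory CSVs, straightness
   filtering, aggregation to species means;
2. morpho     — spination index / relative leg length, assembly of the
   species trait table with the ecology codings;
3. mk         — ER/ARD/Dollo fits of web evolution, AICc weights,
   stochastic character maps with loss/gain counts;
4. contmodels — BM/OU/EB/lambda model tables for sprint speed and
   spination;
5. pgls       — phylogenetic regressions of each trait on each ecological
   predictor, looped over the supplied topologies;
6. effects    — bootstrap group mean-difference effect sizes.

Species with trait data but no tip in the tree are pruned, and tips
without trait data are pruned from the tree, both with a report —
generalizing how the study dropped taxa lacking trait data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contmodels, effects, kinematics, mk, morpho, pgls, treeio

log = logging.getLogger("marronoid")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    tree_files: list[str]
    trajectory_dir: str | None = None
    morpho_file: str | None = None
    ecology_file: str | None = None
    trait_table_file: str | None = None     # precomputed; skips stages 1-2
    out_dir: str = "results"
    run_kinematics: bool = True
    run_morpho: bool = True
    run_mk: bool = True
    run_contmodels: bool = True
    run_pgls: bool = True
    run_effects: bool = True
    straightness_threshold: float = 0.9
    knots_rule: str = "half_plus_one"
    mk_models: tuple[str, ...] = ("ER", "ARD", "DOLLO")
    n_maps: int = 100
    cont_models: tuple[str, ...] = ("BM", "OU", "EB", "lambda")
    predictors: tuple[str, ...] = ("web", "cribellar", "ground")
    traits: tuple[str, ...] = ("sprint_rel", "spination")
    pgls_methods: dict = field(default_factory=lambda: {
        "sprint_rel": "lambda", "spination": "OU"})
    bootstrap_B: int = 5000
    seed: int = 1

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns a dict of result tables and writes
    them as CSV under ``config.out_dir``. Deterministic given config.seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    trees = {Path(f).stem: treeio.read_newick(Path(f).read_text())
             for f in config.tree_files}
    if not trees:
        raise ValueError("at least one tree is required")

    # stage 1: kinematics ------------------------------------------------
    species_speeds = None
    if config.run_kinematics and config.trajectory_dir:
        summaries, dropped = [], []
        for f in sorted(Path(config.trajectory_dir).glob("*.csv")):
            traj = kinematics.read_trajectory_csv(f)
            s = kinematics.process_trial(
                traj, straightness_threshold=config.straightness_threshold)
            if s is None:
                dropped.append(f.name)
                log.info("dropped trial %s (straightness filter)", f.name)
            else:
                summaries.append(s)
        ind, species_speeds = kinematics.aggregate(summaries)
        trials = pd.DataFrame([vars(s) for s in summaries])
        trials.to_csv(out / "trial_summaries.csv", index=False)
        ind.to_csv(out / "individual_summaries.csv", index=False)
        species_speeds.to_csv(out / "species_speeds.csv", index=False)
        results["trials"] = trials
        results["individuals"] = ind
        results["species_speeds"] = species_speeds
        results["dropped_trials"] = dropped

    # stage 2: morpho + trait table -------------------------------------
    first_tree = next(iter(trees.values()))
    if config.trait_table_file:
        traits = pd.read_csv(config.trait_table_file)
        dropped_species = sorted(set(traits["species"]) - set(first_tree.tip_labels))
        traits = traits[traits["species"].isin(first_tree.tip_labels)]
    elif config.run_morpho and config.morpho_file:
        records = morpho.records_from_long(pd.read_csv(config.morpho_file))
        ecology = (pd.read_csv(config.ecology_file)
                   if config.ecology_file else None)
        traits, dropped_species = morpho.species_trait_table(
            records, species_speeds, ecology, first_tree.tip_labels)
    else:
        raise ValueError("need either a trait table or a morpho measurement file")
    for sp in dropped_species:
        log.info("species %s has trait data but no tip in the tree; dropped", sp)
    traits = traits.reset_index(drop=True)
    traits.to_csv(out / "trait_table.csv", index=False)
    results["traits"] = traits
    results["dropped_species"] = dropped_species

    # prune trees to species with data
    have = [s for s in first_tree.tip_labels if s in set(traits["species"])]
    pruned_tips = sorted(set(first_tree.tip_labels) - set(have))
    for t in pruned_tips:
        log.info("tip %s lacks trait data; pruned from tree", t)
    trees = {k: (v.prune_to(have) if set(have) != set(v.tip_labels) else v)
             for k, v in trees.items()}
    results["pruned_tips"] = pruned_tips
    tr = traits.set_index("species")

    # stage 3: Mk models + simmap ----------------------------------------
    if config.run_mk and "web" in traits.columns:
        mk_rows, map_rows = [], []
        for tname, tree in trees.items():
            tips = {s: int(tr.loc[s, "web"]) for s in tree.tip_labels}
            fits = [mk.fit_mk(tree, tips, c, seed=config.seed)
                    for c in config.mk_models]
            for f, w in zip(fits, mk.aicc_weights(fits)):
                f.weight = float(w)
                mk_rows.append({
                    "topology": tname, "model": f.model.constraint,
                    "q_gain": f.model.q01, "q_loss": f.model.q10,
                    "logLik": f.loglik, "AICc": f.aicc, "weight": f.weight,
                })
            for f in fits:
                maps = mk.sample_maps(tree, tips, f.model, n_maps=config.n_maps,
                                      seed=config.seed)
                s = mk.summarize_maps(maps)
                map_rows.append({"topology": tname,
                                 "model": f.model.constraint, **s})
        results["mk_fits"] = pd.DataFrame(mk_rows)
        results["simmap_counts"] = pd.DataFrame(map_rows)
        results["mk_fits"].to_csv(out / "mk_fits.csv", index=False)
        results["simmap_counts"].to_csv(out / "simmap_counts.csv", index=False)

    def _tree_for(tree, trait):
        """Prune tips whose value for this trait is missing (e.g. every
        trial failed the straightness filter)."""
        ok = [s for s in tree.tip_labels if np.isfinite(tr.loc[s, trait])]
        if len(ok) < len(tree.tip_labels):
            log.info("trait %s: dropping %d species without data", trait,
                     len(tree.tip_labels) - len(ok))
        return tree if len(ok) == len(tree.tip_labels) else tree.prune_to(ok)

    # stage 4: continuous models -----------------------------------------
    if config.run_contmodels:
        tabs = []
        for tname, tree_full in trees.items():
            for trait in config.traits:
                if trait not in traits.columns:
                    continue
                tree = _tree_for(tree_full, trait)
                vals = {s: float(tr.loc[s, trait]) for s in tree.tip_labels}
                fits = contmodels.fit_all(tree, vals, config.cont_models)
                tab = contmodels.model_table(fits)
                tab.insert(0, "trait", trait)
                tab.insert(0, "topology", tname)
                tabs.append(tab)
        if tabs:
            results["cont_model_tables"] = pd.concat(tabs, ignore_index=True)
            results["cont_model_tables"].to_csv(out / "cont_models.csv", index=False)

    # stage 5: PGLS -------------------------------------------------------
    if config.run_pgls:
        rows = []
        for tname, tree_full in trees.items():
            for trait in config.traits:
                if trait not in traits.columns:
                    continue
                method = config.pgls_methods.get(trait, "lambda")
                tree = _tree_for(tree_full, trait)
                yv = {s: float(tr.loc[s, trait]) for s in tree.tip_labels}
                for pred in config.predictors:
                    if pred not in traits.columns:
                        continue
                    xv = {s: float(tr.loc[s, pred]) for s in tree.tip_labels}
                    try:
                        fit = pgls.phylo_lm(tree, yv, xv, method=method,
                                            names=[pred])
                    except ValueError as exc:   # e.g. predictor constant
                        log.warning("pgls %s ~ %s skipped: %s", trait, pred, exc)
                        continue
                    rep = pgls.group_contrast_report(fit, pred)
                    rows.append({"topology": tname, "trait": trait, **rep})
        results["pgls"] = pd.DataFrame(rows)
        results["pgls"].to_csv(out / "pgls_contrasts.csv", index=False)

    # stage 6: effect sizes ------------------------------------------------
    if config.run_effects:
        rows = []
        for trait in config.traits:
            if trait not in traits.columns:
                continue
            for pred in config.predictors:
                if pred not in traits.columns:
                    continue
                sub = traits.dropna(subset=[trait, pred])
                try:
                    res = effects.bootstrap_ci(
                        sub[trait].to_numpy(), sub[pred].to_numpy(),
                        B=config.bootstrap_B, seed=config.seed)
                except ValueError as exc:       # e.g. an empty group
                    log.warning("effect size %s by %s skipped: %s",
                                trait, pred, exc)
                    continue
                rows.append({"trait": trait, "predictor": pred,
                             **{k: v for k, v in vars(res).items()
                                if k != "group_labels"}})
        results["effect_sizes"] = pd.DataFrame(rows)
        results["effect_sizes"].to_csv(out / "effect_sizes.csv", index=False)

    with open(out / "run_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)
    return results
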