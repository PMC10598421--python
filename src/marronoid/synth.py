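"""Synthetic study generator: trees, trait data and tracking trajectories.

Every input the comparative pipeline consumes can be generated here with
known ground truth, which is what all recovery and calibration tests run
on. Components:

* birth-death trees on extant tips (ultrametric, in arbitrary time units);
* binary traits evolved forward under a 2-state Markov process, returning
  both tip states and the full per-branch event history;
* continuous traits drawn from the exact BM/OU/EB/lambda multivariate
  normal, optionally with a binary-predictor mean shift (regression data);
* running trajectories: a smooth speed profile integrated to a path, plus
  a sinusoidal body-centre (gait) oscillation and Gaussian pixel jitter,
  packaged with the metadata (fps, scale, body length) the kinematics
  stage needs.

All generators are deterministic in their seed; each call derives its own
stream from (seed, call-tag) so adding calls does not perturb other
outputs.

Default trajectory conditions emulate a lab runway recording: 500 fps,
100 px/cm, 1 cm spider, a triangular speed profile peaking at 40 cm/s
over 1 s, gait oscillation of amplitude 0.15 body lengths at 8 Hz and
2 px tracking jitter (about 2% of body length, a typical localization
accuracy for a soft-bodied landmark such as the abdomen edge).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import treeio
from .kinematics import Trajectory
from .mk import RateModel
from .treeio import Phylogeny

__all__ = [
    "TrajectoryConfig",
    "simulate_tree",
    "simulate_discrete",
    "simulate_continuous",
    "simulate_regression_dataset",
    "simulate_trajectory",
    "make_fixture",
]

RETRY_CAP = 1000


def _rng(seed, tag: str) -> np.random.Generator:
    # crc32, not hash(): stable across processes
    tag_key = zlib.crc32(tag.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag_key]))


# -- trees ---------------------------------------------------------------

def simulate_tree(n_tips: int, birth: float = 1.0, death: float = 0.0,
                  seed: int = 0) -> Phylogeny:
    """Birth-death tree conditioned on ``n_tips`` extant tips by the simple
    stopping rule: grow forward until the lineage count first reaches
    n_tips, then extend all extant branches by one more waiting time.
    Resamples on total extinction, up to a cap."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not birth > death or death < 0:
        raise ValueError("require birth > death >= 0")
    rng = _rng(seed, "tree")
    for _ in range(RETRY_CAP):
        nwk = _grow_tree(n_tips, birth, death, rng)
        if nwk is not None:
            return treeio.read_newick(nwk)
    raise RuntimeError(f"all lineages went extinct in {RETRY_CAP} attempts")


def _grow_tree(n_tips, birth, death, rng):
    next_id = [0]

    def new_node():
        next_id[0] += 1
        return {"id": next_id[0], "children": [], "t_birth": 0.0, "t_end": None}

    root = new_node()
    active = [root]
    t = 0.0
    while active:
        n = len(active)
        if n >= n_tips:
            t += rng.exponential(1.0 / (n * (birth + death)))
            break
        t += rng.exponential(1.0 / (n * (birth + death)))
        node = active[rng.integers(n)]
        node["t_end"] = t
        active.remove(node)
        if rng.random() < birth / (birth + death):
            for _ in range(2):
                ch = new_node()
                ch["t_birth"] = t
                node["children"].append(ch)
                active.append(ch)
        # else: extinction; node simply ends
    if len(active) < n_tips:
        return None
    for node in active:
        node["t_end"] = t
    label = [0]

    def render(node):
        bl = node["t_end"] - node["t_birth"]
        if node["children"]:
            alive = [render(c) for c in node["children"]]
            alive = [a for a in alive if a is not None]
            if not alive:
                return None
            if len(alive) == 1:      # extinct sister: splice through
                lab, rest = alive[0].rsplit(":", 1)
                return f"{lab}:{float(rest) + bl}"
            return f"({','.join(alive)}):{bl}"
        if node["t_end"] < t:        # extinct tip: drop
            return None
        label[0] += 1
        return f"t{label[0]}:{bl}"

    body = render(root)
    if body is None or body.count(",") + 1 != n_tips:
        return None
    if not body.startswith("("):
        return None
    # root branch length is meaningless; strip it
    body = body.rsplit(":", 1)[0] if body.rfind(":") > body.rfind(")") else body
    return body + ";"


# -- discrete traits -----------------------------------------------------

@dataclass
class DiscreteHistory:
    """Ground-truth character history from a forward simulation."""

    tip_states: dict[str, int]
    node_states: np.ndarray
    events: dict[int, list[tuple[float, int, int]]]

    @property
    def n_gain(self) -> int:
        return sum(1 for evs in self.events.values() for _, a, b in evs
                   if a == 0 and b == 1)

    @property
    def n_loss(self) -> int:
        return sum(1 for evs in self.events.values() for _, a, b in evs
                   if a == 1 and b == 0)

    @property
    def n_events(self) -> int:
        return sum(len(evs) for evs in self.events.values())


def simulate_discrete(tree: Phylogeny, model: RateModel, seed: int = 0,
                      root_state: int | None = None) -> DiscreteHistory:
    """Evolve a binary character root -> tips by exponential waiting times;
    returns tip states plus the full event history (the oracle for
    stochastic-map tests)."""
    rng = _rng(seed, "discrete")
    Q = model.Q
    rates = -np.diag(Q)
    k = Q.shape[0]
    states = np.full(tree.n_nodes, -1, dtype=int)
    if root_state is None:
        states[tree.root] = rng.choice(k, p=model.pi)
    else:
        states[tree.root] = root_state
    events: dict[int, list[tuple[float, int, int]]] = {}
    for v in tree.postorder()[::-1]:       # preorder
        for c in tree.children[v]:
            s, now, evs = states[v], 0.0, []
            t = tree.blen[c]
            while rates[s] > 0:
                now += rng.exponential(1.0 / rates[s])
                if now >= t:
                    break
                w = Q[s].copy()
                w[s] = 0.0
                nxt = int(rng.choice(k, p=w / w.sum()))
                evs.append((now, s, nxt))
                s = nxt
            states[c] = s
            events[c] = evs
    tips = {lab: int(states[i]) for i, lab in enumerate(tree.tip_labels)}
    return DiscreteHistory(tip_states=tips, node_states=states, events=events)


# -- continuous traits ---------------------------------------------------

def simulate_continuous(tree: Phylogeny, model: str = "BM",
                        params: dict | None = None, seed: int = 0,
                        size: int = 1) -> np.ndarray:
    """Tip values from MVN(z0, sigma2 * T(C)); shape (n_tips,) or
    (size, n_tips). params: sigma2, z0 and the model shape parameter."""
    params = dict(params or {})
    sigma2 = params.get("sigma2", 1.0)
    z0 = params.get("z0", 0.0)
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    C = treeio.vcv(tree)
    V = treeio.transform_covariance(C, model, params, tree.tree_height)
    rng = _rng(seed, "continuous")
    n = tree.n_tips
    if sigma2 == 0:
        out = np.full((size, n), z0)
    else:
        L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(n))
        out = z0 + rng.standard_normal((size, n)) @ L.T
    return out[0] if size == 1 else out


def simulate_regression_dataset(tree: Phylogeny, groups, beta: float,
                                model: str = "BM", params: dict | None = None,
                                beta0: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """y = beta0 + beta * group + e, e ~ MVN(0, sigma2 * T(C)); ``groups``
    is a 0/1 label per tip (dict keyed by label or array in tip order)."""
    if isinstance(groups, dict):
        g = np.array([int(groups[t]) for t in tree.tip_labels])
    else:
        g = np.asarray(groups, dtype=int)
        if len(g) != tree.n_tips:
            raise ValueError("groups length does not match tip count")
    eps = simulate_continuous(tree, model, {**(params or {}), "z0": 0.0}, seed=seed)
    y = beta0 + beta * g + eps
    return pd.DataFrame({"species": tree.tip_labels, "group": g, "y": y})


# -- trajectories --------------------------------------------------------

@dataclass
class TrajectoryConfig:
    """Study conditions for one synthetic running trial."""

    seed: int = 0
    fps: float = 500.0
    px_per_cm: float = 100.0
    body_length_cm: float = 1.0
    duration_s: float = 1.0
    v_max_cm_s: float = 40.0            # peak of the speed profile
    profile: str = "triangular"         # or 'constant'
    osc_amplitude_bl: float = 0.15      # gait oscillation, body lengths
    osc_freq_hz: float = 8.0
    jitter_px: float = 2.0              # tracking noise sd
    species: str = "sp1"
    individual: str = "i1"
    trial: str = "t1"


def _speed_profile(cfg: TrajectoryConfig, t: np.ndarray) -> np.ndarray:
    if cfg.profile == "constant":
        return np.full_like(t, cfg.v_max_cm_s)
    if cfg.profile == "triangular":
        half = cfg.duration_s / 2.0
        return cfg.v_max_cm_s * (1.0 - np.abs(t - half) / half)
    raise ValueError(f"unknown profile {cfg.profile!r}")


def simulate_trajectory(cfg: TrajectoryConfig) -> tuple[Trajectory, np.ndarray]:
    """One tracked trial. Returns (Trajectory, true instantaneous speed at
    frame times). x integrates the speed profile; the gait oscillation is a
    sinusoid (lateral in y, half-amplitude fore-aft in x); jitter is iid
    Gaussian pixel noise on both coordinates."""
    n = int(round(cfg.duration_s * cfg.fps)) + 1
    if n < 10:
        raise ValueError("duration x fps must give at least 10 frames")
    rng = _rng(cfg.seed, "trajectory")
    t = np.arange(n) / cfg.fps
    v_true = _speed_profile(cfg, t)
    x_cm = np.concatenate([[0.0], np.cumsum((v_true[1:] + v_true[:-1]) / 2.0 / cfg.fps)])
    amp = cfg.osc_amplitude_bl * cfg.body_length_cm
    phase = rng.uniform(0, 2 * np.pi)
    osc_x = 0.5 * amp * np.sin(2 * np.pi * cfg.osc_freq_hz * t + phase + np.pi / 4)
    osc_y = amp * np.sin(2 * np.pi * cfg.osc_freq_hz * t + phase)
    x_px = (x_cm + osc_x) * cfg.px_per_cm + cfg.jitter_px * rng.standard_normal(n)
    y_px = (1.0 + osc_y) * cfg.px_per_cm + cfg.jitter_px * rng.standard_normal(n)
    traj = Trajectory(frame=np.arange(n), x_px=x_px, y_px=y_px, fps=cfg.fps,
                      px_per_cm=cfg.px_per_cm, body_length_cm=cfg.body_length_cm,
                      species=cfg.species, individual=cfg.individual,
                      trial=cfg.trial)
    return traj, v_true


# -- complete fixtures ---------------------------------------------------

def make_fixture(outdir, n_species: int = 60, seed: int = 0,
                 q_gain: float = 1.0, q_loss: float = 1.0,
                 n_individuals: int = 2, n_trials: int = 2) -> dict:
    """Write a complete synthetic data directory (tree, ecology table,
    morphometrics, trajectories) that `run_pipeline` can consume; returns
    the ground truth used to generate it.

    Rates are per 50 Myr of branch length (the tree is rescaled to height
    50): the default one change per lineage per tree height emulates a
    highly dynamic foraging-mode history with on the order of 20
    transitions across the clade."""
    from pathlib import Path

    from .kinematics import write_trajectory_csv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(n_species, birth=1.0, death=0.2, seed=seed)
    # rescale to height 50 (a plausible crown age in Myr)
    tree.blen *= 50.0 / tree.tree_height
    tree._depths = None
    (out / "tree.nwk").write_text(treeio.write_newick(tree) + "\n")

    web = simulate_discrete(
        tree, RateModel(q01=q_gain / 50.0, q10=q_loss / 50.0), seed=seed + 1)
    crib = simulate_discrete(
        tree, RateModel(q01=0.2 / 50.0, q10=0.4 / 50.0), seed=seed + 2)
    ground = simulate_discrete(
        tree, RateModel(q01=0.3 / 50.0, q10=0.3 / 50.0), seed=seed + 3)
    ecology = pd.DataFrame({
        "species": tree.tip_labels,
        "web": [web.tip_states[s] for s in tree.tip_labels],
        "cribellar": [crib.tip_states[s] for s in tree.tip_labels],
        "ground": [ground.tip_states[s] for s in tree.tip_labels],
    })
    ecology.to_csv(out / "ecology.csv", index=False)

    # species-level true sprint speeds (bl/s), lognormal-ish via lambda model
    lsprint = simulate_continuous(
        tree, "lambda",
        {"sigma2": 0.3 / 50.0, "z0": np.log(30.0), "lambda": 0.7},
        seed=seed + 4)
    sprint_true = dict(zip(tree.tip_labels, np.exp(lsprint)))
    spin = simulate_continuous(
        tree, "OU", {"sigma2": 0.02, "z0": 0.25, "alpha": 2.0 / 50.0},
        seed=seed + 5)
    spination_true = dict(zip(tree.tip_labels, np.clip(spin, 0.01, None)))

    rng = _rng(seed, "fixture")
    trajdir = out / "trajectories"
    trajdir.mkdir(exist_ok=True)
    for s, species in enumerate(tree.tip_labels):
        bl = float(rng.uniform(0.4, 1.2))
        for i in range(n_individuals):
            for tr in range(n_trials):
                v_peak = sprint_true[species] * bl * float(rng.uniform(0.85, 1.0))
                cfg = TrajectoryConfig(
                    seed=seed * 100003 + s * 97 + i * 7 + tr,
                    body_length_cm=bl, v_max_cm_s=v_peak,
                    species=species, individual=f"{species}_i{i + 1}",
                    trial=f"t{tr + 1}")
                traj, _ = simulate_trajectory(cfg)
                write_trajectory_csv(traj, trajdir / f"{species}_i{i + 1}_t{tr + 1}.csv")

    rows = []
    for s, species in enumerate(tree.tip_labels):
        seg = rng.uniform(1.0, 4.0, size=3)          # front-leg segments, mm
        spines = spination_true[species] * seg.sum()
        hind = rng.uniform(1.5, 5.0, size=3)
        cw = float(rng.uniform(1.0, 3.0))
        spec = f"{species}_m1"
        for j, L in enumerate(seg):
            rows.append((spec, species, f"front_segment_{j + 1}", L))
        rows.append((spec, species, "spine_1", spines))
        for j, L in enumerate(hind):
            rows.append((spec, species, f"hind_segment_{j + 1}", L))
        rows.append((spec, species, "carapace_width", cw))
        rows.append((spec, species, "body_length", float(rng.uniform(4.0, 12.0))))
    pd.DataFrame(rows, columns=["specimen", "species", "structure",
                                "measurement_mm"]).to_csv(
        out / "morphometrics.csv", index=False)

    return {
        "tree": tree, "web_history": web, "sprint_true": sprint_true,
        "spination_true": spination_true, "ecology": ecology,
    }
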