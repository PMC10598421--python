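"""Two-state Markov (Mk) models of web evolution and stochastic character maps.

States are coded 0 = no web (cursorial) and 1 = web-building. Three model
constraints are supported:

* ``ER``    — equal rates, one free parameter (q01 = q10);
* ``ARD``   — all rates different, two free parameters;
* ``DOLLO`` — web re-evolution suppressed (gain rate q01 = 0), one free
  parameter; the root is fixed in state 1 since any observed web then
  requires a web-bearing ancestor.

The likelihood core (Felsenstein pruning) accepts any number of states, but
the fitting/mapping surface is binary. Stochastic character maps sample
explicit branch histories conditional on tip data, which is what lets us
count web losses (1 -> 0) and gains (0 -> 1) over the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

from .infocrit import aicc, aicc_weights
from .treeio import Phylogeny

__all__ = [
    "RateModel",
    "MkFit",
    "StochasticMap",
    "mk_loglik",
    "fit_mk",
    "ancestral_posteriors",
    "sample_maps",
    "aicc_weights",
]

RATE_BOUNDS = (1e-8, 1e3)


@dataclass
class RateModel:
    """2-state rate matrix with root distribution.

    q01 is the gain rate (0 -> 1, web gained), q10 the loss rate.
    """

    q01: float
    q10: float
    pi: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    constraint: str = "ARD"

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be non-negative")
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("root distribution must sum to 1")
        c = self.constraint.upper()
        if c == "ER" and not np.isclose(self.q01, self.q10):
            raise ValueError("ER requires q01 == q10")
        if c == "DOLLO" and self.q01 != 0:
            raise ValueError("DOLLO requires gain rate q01 == 0")

    @property
    def Q(self) -> np.ndarray:
        return np.array([[-self.q01, self.q01], [self.q10, -self.q10]])

    @property
    def k_free(self) -> int:
        return {"ER": 1, "ARD": 2, "DOLLO": 1}[self.constraint.upper()]


def transition_probs(q01: float, q10: float, t: np.ndarray) -> np.ndarray:
    """Closed-form 2-state P(t) = exp(Qt) for an array of times -> (n, 2, 2)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    s = q01 + q10
    P = np.empty((len(t), 2, 2))
    if s == 0:
        P[:] = np.eye(2)
        return P
    e = np.exp(-s * t)
    p0, p1 = q10 / s, q01 / s          # stationary distribution
    P[:, 0, 0] = p0 + p1 * e
    P[:, 0, 1] = p1 - p1 * e
    P[:, 1, 0] = p0 - p0 * e
    P[:, 1, 1] = p1 + p0 * e
    return P


def _transition_probs_general(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.stack([expm(Q * ti) for ti in np.atleast_1d(t)])


def _tip_partials(tree: Phylogeny, tips: dict[str, int], k: int) -> np.ndarray:
    L = np.zeros((tree.n_nodes, k))
    idx = tree.tip_index
    unknown = set(tips) - set(idx)
    if unknown:
        raise KeyError(f"tip states given for labels not in tree: {sorted(unknown)}")
    missing = set(idx) - set(tips)
    if missing:
        raise KeyError(f"no state for tips: {sorted(missing)}")
    for lab, state in tips.items():
        L[idx[lab], int(state)] = 1.0
    return L


def _pruning(tree: Phylogeny, tips: dict[str, int], model: RateModel
             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled conditional likelihoods. Returns (partials, P per branch,
    accumulated log-scaler)."""
    k = len(model.pi)
    if k == 2:
        P = transition_probs(model.q01, model.q10, tree.blen)
    else:  # pragma: no cover - generality hook
        P = _transition_probs_general(model.Q, tree.blen)
    L = _tip_partials(tree, tips, k)
    logscale = 0.0
    for v in tree.postorder():
        if v < tree.n_tips:
            continue
        part = np.ones(k)
        for c in tree.children[v]:
            part = part * (P[c] @ L[c])
        tot = part.sum()
        if tot <= 0:
            return L, P, -np.inf
        L[v] = part / tot
        logscale += np.log(tot)
    return L, P, logscale


def mk_loglik(tree: Phylogeny, tips: dict[str, int], model: RateModel) -> float:
    """Felsenstein-pruning log-likelihood of binary tip states under ``model``.

    Returns -inf when the data are impossible under the model (e.g. mixed
    tip states with all rates zero).
    """
    L, _, logscale = _pruning(tree, tips, model)
    if not np.isfinite(logscale):
        return -np.inf
    lik = float(model.pi @ L[tree.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


def _make_model(constraint: str, rates: np.ndarray,
                root_pi: np.ndarray | None) -> RateModel:
    c = constraint.upper()
    if c == "ER":
        q01 = q10 = rates[0]
    elif c == "DOLLO":
        q01, q10 = 0.0, rates[0]
    elif c == "ARD":
        q01, q10 = rates
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    if root_pi is None:
        root_pi = np.array([0.0, 1.0]) if c == "DOLLO" else np.array([0.5, 0.5])
    return RateModel(q01=q01, q10=q10, pi=root_pi, constraint=c)


@dataclass
class MkFit:
    model: RateModel
    loglik: float
    aicc: float
    n: int
    weight: float = np.nan
    converged: bool = True

    @property
    def k_free(self) -> int:
        return self.model.k_free


def fit_mk(tree: Phylogeny, tips: dict[str, int], constraint: str = "ER",
           root_pi: np.ndarray | None = None, n_starts: int = 5,
           seed: int | None = None) -> MkFit:
    """Maximum-likelihood rates under the given constraint.

    Rates are optimized on the log scale within [1e-8, 1e3] per unit branch
    length; multi-start for the 2-parameter ARD model. Warns (not errors)
    when one state has < 2 tips, where rates are weakly identifiable.
    """
    counts = np.bincount([int(s) for s in tips.values()], minlength=2)
    if counts.min() < 2:
        import warnings
        warnings.warn("fewer than 2 tips in one state; rate estimates may be unstable")
    c = constraint.upper()
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def nll(logr: np.ndarray) -> float:
        m = _make_model(c, np.exp(np.atleast_1d(logr)), root_pi)
        ll = mk_loglik(tree, tips, m)
        return -ll if np.isfinite(ll) else 1e12

    if c in ("ER", "DOLLO"):
        res = minimize_scalar(lambda z: nll(np.array([z])), bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-8})
        best_x, best_f, ok = np.array([res.x]), res.fun, res.success
    else:
        rng = np.random.default_rng(seed)
        starts = [np.log([0.1, 0.1])] + [rng.uniform(np.log(1e-3), np.log(10.0), 2)
                                         for _ in range(n_starts - 1)]
        best_x, best_f, ok = None, np.inf, False
        for x0 in starts:
            res = minimize(nll, x0, method="L-BFGS-B",
                           bounds=[(lo, hi)] * 2)
            if res.fun < best_f:
                best_x, best_f, ok = res.x, res.fun, bool(res.success)
        if best_x is None:  # pragma: no cover
            raise RuntimeError("ARD optimization failed from all starts")
    model = _make_model(c, np.exp(best_x), root_pi)
    ll = -best_f
    n = tree.n_tips
    return MkFit(model=model, loglik=ll, aicc=aicc(ll, model.k_free, n),
                 n=n, converged=ok)


def ancestral_posteriors(tree: Phylogeny, tips: dict[str, int],
                         model: RateModel) -> np.ndarray:
    """Marginal posterior state probabilities at every node (tips included),
    via the up-down (re-rooting) algorithm. Rows follow node indices and
    each sums to 1."""
    k = len(model.pi)
    L, P, logscale = _pruning(tree, tips, model)
    if not np.isfinite(logscale) or model.pi @ L[tree.root] <= 0:
        raise ValueError("data impossible under the model; posteriors undefined")
    U = np.zeros_like(L)               # "outside" partials, root prior folded in
    U[tree.root] = model.pi
    for v in tree.postorder()[::-1]:   # preorder: parents before children
        for c in tree.children[v]:
            sib = np.ones(k)
            for w in tree.children[v]:
                if w != c:
                    sib = sib * (P[w] @ L[w])
            out = U[v] * sib
            U[c] = out @ P[c]          # sum over parent state
            tot = U[c].sum()
            if tot > 0:
                U[c] = U[c] / tot
    post = L * U
    post = post / post.sum(axis=1, keepdims=True)
    return post


@dataclass
class StochasticMap:
    """One sampled character history: states at nodes and, per branch, the
    ordered list of (time-from-branch-start, from_state, to_state) events."""

    node_states: np.ndarray
    events: dict[int, list[tuple[float, int, int]]]

    @property
    def n_gain(self) -> int:
        return sum(1 for evs in self.events.values()
                   for _, a, b in evs if a == 0 and b == 1)

    @property
    def n_loss(self) -> int:
        return sum(1 for evs in self.events.values()
                   for _, a, b in evs if a == 1 and b == 0)


def _sample_path_rejection(a: int, b: int, t: float, Q: np.ndarray,
                           rng: np.random.Generator,
                           max_tries: int = 1000) -> list[tuple[float, int, int]] | None:
    """Endpoint-conditioned CTMC path by forward rejection; when the
    endpoints differ the first event time is drawn from a truncated
    exponential so paths with >= 1 event are proposed (Nielsen's trick)."""
    k = Q.shape[0]
    rates = -np.diag(Q)
    for _ in range(max_tries):
        events: list[tuple[float, int, int]] = []
        state, now = a, 0.0
        if a != b:
            r = rates[a]
            if r <= 0:
                return None
            u = rng.random()
            now = -np.log1p(-u * (1.0 - np.exp(-r * t))) / r
            nxt = _draw_next(state, Q, rng)
            events.append((now, state, nxt))
            state = nxt
        while True:
            r = rates[state]
            if r <= 0:
                break
            now = now + rng.exponential(1.0 / r)
            if now >= t:
                break
            nxt = _draw_next(state, Q, rng)
            events.append((now, state, nxt))
            state = nxt
        if state == b:
            return events
    return None


def _draw_next(state: int, Q: np.ndarray, rng: np.random.Generator) -> int:
    w = Q[state].copy()
    w[state] = 0.0
    return int(rng.choice(len(w), p=w / w.sum()))


def _sample_path_uniformization(a: int, b: int, t: float, Q: np.ndarray,
                                rng: np.random.Generator) -> list[tuple[float, int, int]]:
    """Exact endpoint-conditioned path via uniformization: dominate the chain
    with a Poisson(mu t) number of candidate jumps, sample the jump count and
    the state bridge under R = I + Q/mu, then drop virtual self-jumps."""
    k = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:
        if a != b:
            raise ValueError("impossible endpoint pair under a zero-rate model")
        return []
    R = np.eye(k) + Q / mu
    Pab = float(expm(Q * t)[a, b])
    if Pab <= 0:
        raise ValueError(f"endpoint pair {a}->{b} impossible under the model")
    # p(n) ~ Poisson(mu t) * R^n[a,b] / Pab
    u = rng.random()
    cum, n = 0.0, -1
    log_poisson = -mu * t
    Rn = np.eye(k)
    Rpows = [Rn]
    term = np.exp(log_poisson)
    while cum < u and n < 10000:
        n += 1
        if n > 0:
            term = term * (mu * t) / n
            Rpows.append(Rpows[-1] @ R)
        cum += term * Rpows[n][a, b] / Pab
    times = np.sort(rng.random(n) * t)
    states = [a]
    for i in range(1, n + 1):
        w = Rpows[1][states[-1]] * Rpows[n - i][:, b]
        states.append(int(rng.choice(k, p=w / w.sum())))
    events = []
    for tt, s0, s1 in zip(times, states[:-1], states[1:]):
        if s0 != s1:
            events.append((float(tt), s0, s1))
    return events


def sample_maps(tree: Phylogeny, tips: dict[str, int], model: RateModel,
                n_maps: int = 100, seed: int | None = None,
                max_rejections: int = 1000) -> list[StochasticMap]:
    """Stochastic character maps: node states drawn from their joint
    conditional distribution (backward sampling on the pruning partials),
    branch histories conditional on endpoints (rejection sampling with a
    uniformization fallback)."""
    k = len(model.pi)
    L, P, logscale = _pruning(tree, tips, model)
    if not np.isfinite(logscale) or model.pi @ L[tree.root] <= 0:
        raise ValueError("zero likelihood: cannot sample maps")
    rng = np.random.default_rng(seed)
    Q = model.Q
    maps: list[StochasticMap] = []
    preorder = tree.postorder()[::-1]
    for _ in range(n_maps):
        states = np.full(tree.n_nodes, -1, dtype=int)
        w = model.pi * L[tree.root]
        states[tree.root] = rng.choice(k, p=w / w.sum())
        for v in preorder:
            for c in tree.children[v]:
                w = P[c][states[v]] * L[c]
                tot = w.sum()
                if tot <= 0:
                    raise ValueError(f"no feasible state for node {c} given parent")
                states[c] = rng.choice(k, p=w / tot)
        events: dict[int, list[tuple[float, int, int]]] = {}
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            a, b = states[tree.parent[v]], states[v]
            path = _sample_path_rejection(a, b, tree.blen[v], Q, rng,
                                          max_tries=max_rejections)
            if path is None:
                path = _sample_path_uniformization(a, b, tree.blen[v], Q, rng)
            events[v] = path
        maps.append(StochasticMap(node_states=states, events=events))
    return maps


def summarize_maps(maps: list[StochasticMap]) -> dict[str, float]:
    gains = np.array([m.n_gain for m in maps], dtype=float)
    losses = np.array([m.n_loss for m in maps], dtype=float)
    return {
        "n_maps": len(maps),
        "mean_gains": float(gains.mean()),
        "mean_losses": float(losses.mean()),
        "sd_gains": float(gains.std(ddof=1)) if len(maps) > 1 else 0.0,
        "sd_losses": float(losses.std(ddof=1)) if len(maps) > 1 else 0.0,
    }
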