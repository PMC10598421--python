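"""Continuous-trait evolutionary models: BM, OU, EB and Pagel's lambda.

Each model is a multivariate normal over the tip trait vector with mean
z0 * 1 and covariance sigma^2 * T(C), where C is the Brownian-motion
shared-path-length matrix and T the model's branch-length transform:

* BM      — T = identity (2 free parameters: sigma^2, z0);
* OU      — fixed-root single-optimum Ornstein-Uhlenbeck, optimum tied to
            z0; attraction alpha (3 parameters);
* EB      — early burst, rate decaying as exp(a t), a <= 0 (3 parameters);
* lambda  — Pagel's lambda scaling of shared history, lambda in [0, 1]
            (3 parameters).

z0 and sigma^2 are profiled analytically (GLS estimators) inside a bounded
one-dimensional search over the shape parameter; models are compared by
AICc weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .infocrit import aicc, aicc_weights
from .treeio import Phylogeny, eb_cov, lambda_cov, ou_cov, rescale_lambda, vcv

__all__ = [
    "ContinuousFit",
    "cont_loglik",
    "fit_continuous",
    "model_table",
    "ancestral_values",
]

MODELS = ("BM", "OU", "EB", "lambda")
K_FREE = {"BM": 2, "OU": 3, "EB": 3, "lambda": 3}


@dataclass
class ContinuousFit:
    model: str
    sigma2: float                 # trait^2 per unit time
    z0: float                     # root value, trait units
    loglik: float
    aicc: float
    n: int
    alpha: float | None = None    # OU attraction, 1/time
    a: float | None = None        # EB exponent, 1/time (<= 0)
    lam: float | None = None      # Pagel's lambda
    weight: float = np.nan

    @property
    def k_free(self) -> int:
        return K_FREE[self.model]

    def shape_param(self) -> float | None:
        return {"OU": self.alpha, "EB": self.a, "lambda": self.lam}.get(self.model)


def _model_cov(C: np.ndarray, model: str, params: dict, T: float) -> np.ndarray:
    m = model.lower()
    if m == "bm":
        return C
    if m == "ou":
        return ou_cov(C, params["alpha"], T)
    if m == "eb":
        return eb_cov(C, params["a"])
    if m == "lambda":
        return lambda_cov(C, params["lambda"])
    raise ValueError(f"unknown model {model!r}")


def _mvn_loglik(y: np.ndarray, V: np.ndarray, z0: float, sigma2: float) -> float:
    n = len(y)
    fac = cho_factor(sigma2 * V, lower=True)
    r = y - z0
    quad = float(r @ cho_solve(fac, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(fac[0]))))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def cont_loglik(tree: Phylogeny, trait: dict[str, float] | np.ndarray,
                model: str, params: dict) -> float:
    """Log density of tip values under the named model; ``params`` must hold
    sigma2, z0 and the model's shape parameter."""
    y = _align(tree, trait)
    C = vcv(tree)
    V = _model_cov(C, model, params, tree.tree_height)
    try:
        return _mvn_loglik(y, V, params["z0"], params["sigma2"])
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance not positive definite") from exc


def _align(tree: Phylogeny, trait) -> np.ndarray:
    if isinstance(trait, (dict, pd.Series)):
        missing = [t for t in tree.tip_labels if t not in trait]
        if missing:
            raise KeyError(f"no trait value for tips: {missing}")
        return np.array([float(trait[t]) for t in tree.tip_labels])
    y = np.asarray(trait, dtype=float)
    if len(y) != tree.n_tips:
        raise ValueError("trait vector length does not match tip count")
    return y


def _profile(y: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """GLS-profiled (z0, sigma2_ML, loglik) for covariance shape V."""
    n = len(y)
    fac = cho_factor(V, lower=True)
    ones = np.ones(n)
    Vi1 = cho_solve(fac, ones)
    z0 = float(ones @ cho_solve(fac, y) / (ones @ Vi1))
    r = y - z0
    quad = float(r @ cho_solve(fac, r))
    sigma2 = quad / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(fac[0]))))
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return z0, sigma2, ll


def fit_continuous(tree: Phylogeny, trait, model: str = "BM") -> ContinuousFit:
    """ML fit of one model. Shape-parameter bounds: lambda in [0, 1],
    alpha in [1e-8, 50]/T, a in [-10/T, 0], with T the tree height."""
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips to fit a trait model")
    y = _align(tree, trait)
    C = vcv(tree)
    T = tree.tree_height
    name = "lambda" if model.lower() == "lambda" else model.upper()
    if name not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    n = tree.n_tips

    if name == "BM":
        z0, s2, ll = _profile(y, C)
        return ContinuousFit("BM", s2, z0, ll, aicc(ll, 2, n), n)

    if name == "OU":
        lo, hi, key = 1e-8 / T, 50.0 / T, "alpha"
        build = lambda p: ou_cov(C, p, T)
    elif name == "EB":
        lo, hi, key = -10.0 / T, -1e-10 / T, "a"
        build = lambda p: eb_cov(C, p)
    else:
        lo, hi, key = 0.0, 1.0, "lambda"
        build = lambda p: lambda_cov(C, p)

    def nll(p: float) -> float:
        try:
            return -_profile(y, build(p))[2]
        except np.linalg.LinAlgError:
            return np.inf

    # coarse grid then local refinement: profile likelihoods here can be flat
    grid = np.linspace(lo, hi, 25)
    vals = [nll(g) for g in grid]
    i = int(np.argmin(vals))
    glo = grid[max(i - 1, 0)]
    ghi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(nll, bounds=(glo, ghi), method="bounded",
                          options={"xatol": 1e-10 * (hi - lo)})
    p = float(res.x) if res.fun <= vals[i] else float(grid[i])
    z0, s2, ll = _profile(y, build(p))
    fit = ContinuousFit(name, s2, z0, ll, aicc(ll, 3, n), n)
    setattr(fit, {"OU": "alpha", "EB": "a", "lambda": "lam"}[name], p)
    return fit


def fit_all(tree: Phylogeny, trait, models=MODELS) -> list[ContinuousFit]:
    fits = [fit_continuous(tree, trait, m) for m in models]
    for f, w in zip(fits, aicc_weights(fits)):
        f.weight = float(w)
    return fits


def model_table(fits: list[ContinuousFit]) -> pd.DataFrame:
    """Ranked comparison table with AICc differences and weights."""
    w = aicc_weights(fits)
    rows = []
    amin = min(f.aicc for f in fits)
    for f, wi in zip(fits, w):
        rows.append({
            "model": f.model, "sigma2": f.sigma2, "z0": f.z0,
            "shape_param": f.shape_param(), "logLik": f.loglik,
            "AICc": f.aicc, "dAICc": f.aicc - amin, "weight": float(wi),
        })
    return (pd.DataFrame(rows)
            .sort_values("AICc", ignore_index=True))


def ancestral_values(tree: Phylogeny, trait, fit: ContinuousFit) -> np.ndarray:
    """Expected trait values at every node under the fitted BM or lambda
    model (two-pass GLS reconstruction). Returns a vector over node indices;
    tip entries equal the observed values."""
    if fit.model not in ("BM", "lambda"):
        raise ValueError("ancestral values supported for BM and lambda fits only")
    work = tree if fit.model == "BM" else rescale_lambda(tree, fit.lam)
    y = _align(tree, trait)
    n = tree.n_nodes
    xhat = np.zeros(n)       # subtree-conditional estimate
    extra = np.zeros(n)      # its variance (in units of branch length)
    for v in work.postorder():
        if v < work.n_tips:
            xhat[v] = y[v]
            extra[v] = 0.0
        else:
            wts = np.array([1.0 / (work.blen[c] + extra[c]) for c in work.children[v]])
            vals = np.array([xhat[c] for c in work.children[v]])
            xhat[v] = float(wts @ vals / wts.sum())
            extra[v] = 1.0 / wts.sum()
    # down pass: fold in the rest of the tree
    rest_val = np.full(n, np.nan)
    rest_var = np.full(n, np.inf)
    marginal = xhat.copy()
    for v in work.postorder()[::-1]:
        kids = work.children[v]
        if v != work.root and np.isfinite(rest_var[v]):
            w1, w2 = 1.0 / rest_var[v], 1.0 / extra[v] if extra[v] > 0 else np.inf
            if np.isinf(w2):
                marginal[v] = xhat[v]
            else:
                marginal[v] = (w1 * rest_val[v] + w2 * xhat[v]) / (w1 + w2)
        for c in kids:
            parts_val, parts_w = [], []
            if v != work.root and np.isfinite(rest_var[v]):
                parts_val.append(rest_val[v])
                parts_w.append(1.0 / rest_var[v])
            for w_ in kids:
                if w_ != c:
                    parts_val.append(xhat[w_])
                    parts_w.append(1.0 / (work.blen[w_] + extra[w_]))
            if parts_w:
                pw = np.array(parts_w)
                pv = np.array(parts_val)
                val = float(pw @ pv / pw.sum())
                var = 1.0 / pw.sum()
                rest_val[c] = val
                rest_var[c] = var + work.blen[c]
    marginal[: work.n_tips] = y
    return marginal
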