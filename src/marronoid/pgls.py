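"""Phylogenetic linear regression with lambda or OU residual structure.

The regression y = X b + e assumes e ~ MVN(0, sigma^2 * V(theta)) where
V(theta) is the Brownian covariance C transformed by either Pagel's lambda
(theta = lambda in [0, 1]) or a fixed-root OU process (theta = alpha > 0).
For each candidate theta the coefficients and sigma^2 are profiled by GLS;
the profile likelihood is then maximized over theta (ML, matching the
default of standard phylogenetic regression software). Coefficient tests
are two-sided t tests with n - p degrees of freedom.

Binary ecological predictors are coded 0/1 with the "absent" level as
baseline (cursorial = 0 / web = 1, ecribellar = 0 / cribellar = 1,
above-ground = 0 / ground = 1), so a positive coefficient means the trait
is larger where the predictor is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from .treeio import Phylogeny, lambda_cov, ou_cov, vcv

__all__ = ["RegressionFit", "phylo_lm", "group_contrast_report"]


@dataclass
class RegressionFit:
    method: str                       # 'lambda' or 'OU_fixed_root'
    param: float                      # fitted lambda or alpha
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    sigma2: float                     # ML residual rate
    loglik: float
    n: int
    p: int

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names, "estimate": self.coef, "se": self.se,
            "t": self.tstat, "p": self.pvalue,
        })


def _gls(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    fac = cho_factor(V, lower=True)
    Vi_X = cho_solve(fac, X)
    Vi_y = cho_solve(fac, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    rss = float(r @ cho_solve(fac, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(fac[0]))))
    return beta, rss, logdet, XtViX


def phylo_lm(tree: Phylogeny, y, X, method: str = "lambda",
             names: list[str] | None = None,
             fixed_param: float | None = None) -> RegressionFit:
    """Fit the phylogenetic regression.

    ``y``: trait per species (dict/Series keyed by tip label, or an array in
    tip order). ``X``: design matrix WITHOUT intercept (added here), same
    keying. ``fixed_param`` skips the theta search (used for lambda = 0,
    which reduces to OLS, or lambda = 1, plain BM-GLS).
    """
    yv = _align_vec(tree, y)
    Xm = _align_mat(tree, X)
    n = len(yv)
    Xm = np.column_stack([np.ones(n), Xm])
    if names is None:
        names = ["(Intercept)"] + [f"x{i}" for i in range(1, Xm.shape[1])]
    else:
        names = ["(Intercept)"] + list(names)
    p = Xm.shape[1]
    if np.linalg.matrix_rank(Xm) < p:
        raise ValueError("design matrix is rank deficient")
    C = vcv(tree)
    m = method.lower()
    if m == "lambda":
        build = lambda th: lambda_cov(C, th)
        lo, hi = 0.0, 1.0
    elif m in ("ou", "ou_fixed_root"):
        if not tree.is_ultrametric:
            raise ValueError("OU residual structure requires an ultrametric tree")
        T = tree.tree_height
        build = lambda th: ou_cov(C, th, T)
        lo, hi = 1e-8 / T, 50.0 / T
    else:
        raise ValueError(f"unknown method {method!r}")

    def nll(th: float) -> float:
        try:
            _, rss, logdet, _ = _gls(yv, Xm, build(th))
        except np.linalg.LinAlgError:
            return np.inf
        s2 = rss / n
        if s2 <= 0:
            return np.inf
        return 0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)

    if fixed_param is not None:
        theta = float(fixed_param)
    else:
        grid = np.linspace(lo, hi, 21)
        vals = [nll(g) for g in grid]
        i = int(np.argmin(vals))
        res = minimize_scalar(nll, bounds=(grid[max(i - 1, 0)], grid[min(i + 1, 20)]),
                              method="bounded")
        theta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    V = build(theta)
    beta, rss, logdet, XtViX = _gls(yv, Xm, V)
    s2_ml = rss / n
    s2_unb = rss / (n - p)
    covb = s2_unb * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(covb))
    tstat = beta / se
    pval = 2.0 * t_dist.sf(np.abs(tstat), df=n - p)
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2_ml) + logdet + n)
    return RegressionFit(method="lambda" if m == "lambda" else "OU_fixed_root",
                         param=theta, names=names, coef=beta, se=se,
                         tstat=tstat, pvalue=pval, sigma2=s2_ml, loglik=ll,
                         n=n, p=p)


def group_contrast_report(fit: RegressionFit, contrast: str,
                          level: float = 0.95) -> dict:
    """One results-table row for a named predictor: coefficient (difference
    in trait units between the coded groups, conditional on the model),
    t-based CI and two-sided p-value."""
    if contrast not in fit.names:
        raise KeyError(f"{contrast!r} not among terms {fit.names}")
    i = fit.names.index(contrast)
    tcrit = t_dist.ppf(0.5 + level / 2.0, df=fit.df_resid)
    return {
        "term": contrast,
        "estimate": float(fit.coef[i]),
        "se": float(fit.se[i]),
        "ci_low": float(fit.coef[i] - tcrit * fit.se[i]),
        "ci_high": float(fit.coef[i] + tcrit * fit.se[i]),
        "t": float(fit.tstat[i]),
        "p": float(fit.pvalue[i]),
        "method": fit.method,
        "param": fit.param,
        "n": fit.n,
    }


def _align_vec(tree: Phylogeny, y) -> np.ndarray:
    if isinstance(y, (dict, pd.Series)):
        return np.array([float(y[t]) for t in tree.tip_labels])
    y = np.asarray(y, dtype=float)
    if len(y) != tree.n_tips:
        raise ValueError("response length does not match tip count")
    return y


def _align_mat(tree: Phylogeny, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return np.column_stack([
            [float(X.loc[t, c]) for t in tree.tip_labels] for c in X.columns
        ])
    if isinstance(X, dict):
        return np.array([[float(X[t])] for t in tree.tip_labels])
    Xm = np.asarray(X, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    if Xm.shape[0] != tree.n_tips:
        raise ValueError("design rows do not match tip count")
    return Xm
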