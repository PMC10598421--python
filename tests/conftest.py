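"""Shared fixtures and independent oracle helpers.

The oracles here deliberately avoid the package's own algorithms: Mk
likelihoods are computed by exhaustive enumeration over internal-node
states with scipy's matrix exponential, and ancestral values / covariances
by explicit path-based MRCA computation and dense joint-normal
conditioning.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from marronoid import synth, treeio
from marronoid.treeio import Phylogeny


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return treeio.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry() -> Phylogeny:
    return treeio.read_newick("(A:1,B:1);")


@pytest.fixture
def six_tip_tree() -> Phylogeny:
    return treeio.read_newick(
        "(((A:1,B:1):1,(C:0.5,D:0.5):1.5):1,(E:2,F:2):1);")


# -- independent oracles -------------------------------------------------

def enumerate_mk_likelihood(tree: Phylogeny, tips: dict[str, int],
                            Q: np.ndarray, pi: np.ndarray) -> float:
    """Mk likelihood by brute-force summation over every assignment of
    states to internal nodes (feasible for <= ~8 tips)."""
    k = Q.shape[0]
    internals = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    P = {v: expm(Q * tree.blen[v]) for v in range(tree.n_nodes) if v != tree.root}
    tip_state = {tree.tip_index[lab]: s for lab, s in tips.items()}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        state = dict(zip(internals, assign))
        state.update(tip_state)
        lik = pi[state[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            lik *= P[v][state[tree.parent[v]], state[v]]
        total += lik
    return total


def node_mrca_depth(tree: Phylogeny, u: int, v: int) -> float:
    """Depth of the MRCA of two nodes by explicit root-path intersection."""
    def path(x):
        out = []
        while x >= 0:
            out.append(x)
            x = tree.parent[x]
        return out
    pu, pv = path(u), set(path(v))
    for x in pu:
        if x in pv:
            return float(tree.depths()[x])
    raise AssertionError("no common ancestor")


def joint_node_cov(tree: Phylogeny) -> np.ndarray:
    """BM covariance over ALL nodes (tips + internals) from pairwise MRCA
    depths; rows/cols follow node indices."""
    n = tree.n_nodes
    C = np.zeros((n, n))
    for u in range(n):
        for v in range(u, n):
            C[u, v] = C[v, u] = node_mrca_depth(tree, u, v)
    return C


def random_small_tree(rng: np.random.Generator, max_tips: int = 6) -> Phylogeny:
    n = int(rng.integers(2, max_tips + 1))
    return synth.simulate_tree(n, birth=1.0, death=0.0,
                               seed=int(rng.integers(2**31)))
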