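"""Phylogeny container, Newick I/O and phylogenetic covariance structure.

The tree is the backbone of every comparative computation in this package:
discrete (Mk) likelihoods walk its branches, and all continuous-trait models
(BM, OU, EB, Pagel's lambda) are multivariate normals whose covariance is a
transform of the shared-path-length matrix ``vcv``.

Branch lengths are in time units (e.g. Myr for a time-calibrated tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeParseError",
    "read_newick",
    "write_newick",
    "vcv",
    "lambda_cov",
    "ou_cov",
    "eb_cov",
    "transform_covariance",
    "rescale_lambda",
]

ULTRAMETRIC_RTOL = 1e-6


class TreeParseError(ValueError):
    """Raised when a Newick string cannot be turned into a valid Phylogeny."""


@dataclass
class Phylogeny:
    """Rooted tree stored as flat arrays.

    Node indices: tips are ``0 .. n_tips-1`` (in the order they appear in the
    Newick string); internal nodes follow. ``parent[root] == -1`` and
    ``blen[root] == 0``. Polytomies are allowed and preserved.
    """

    parent: np.ndarray            # (n_nodes,) int, -1 at root
    blen: np.ndarray              # (n_nodes,) float, 0.0 at root
    tip_labels: list[str]
    children: list[list[int]] = field(repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeParseError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise TreeParseError("tip labels are not unique")
        nonroot = np.arange(self.n_nodes) != self.root
        if np.any(self.blen[nonroot] <= 0):
            bad = np.flatnonzero(nonroot & (self.blen <= 0))
            raise TreeParseError(
                f"non-positive branch length at node(s) {bad.tolist()}; "
                "collapse zero-length branches upstream or fix the tree"
            )
        self._postorder: np.ndarray | None = None
        self._depths: np.ndarray | None = None

    # -- basic structure -------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(order[::-1], dtype=int)
        return self._postorder

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths for every node."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for v in self.postorder()[::-1]:       # preorder
                p = self.parent[v]
                if p >= 0:
                    d[v] = d[p] + self.blen[v]
            self._depths = d
        return self._depths

    @property
    def tree_height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    @property
    def is_ultrametric(self) -> bool:
        td = self.depths()[: self.n_tips]
        h = td.max()
        return bool(np.all(np.abs(td - h) <= ULTRAMETRIC_RTOL * max(h, 1.0)))

    @property
    def total_branch_length(self) -> float:
        return float(self.blen.sum())

    # -- editing ---------------------------------------------------------
    def prune_to(self, keep: list[str]) -> "Phylogeny":
        """Subtree restricted to ``keep`` tips; unifurcations are collapsed
        by summing branch lengths. Raises KeyError on unknown labels."""
        idx = self.tip_index
        missing = [k for k in keep if k not in idx]
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        keep_set = {idx[k] for k in keep}
        alive = np.zeros(self.n_nodes, dtype=bool)
        for v in self.postorder():
            if v < self.n_tips:
                alive[v] = v in keep_set
            else:
                alive[v] = any(alive[c] for c in self.children[v])
        # rebuild via newick text (simple and safe for analysis-scale trees)
        def render(v: int) -> str | None:
            if v < self.n_tips:
                return (f"{_quote(self.tip_labels[v])}:{float(self.blen[v])!r}"
                        if alive[v] else None)
            parts = [render(c) for c in self.children[v]]
            parts = [p for p in parts if p is not None]
            if not parts:
                return None
            if len(parts) == 1:
                # collapse unifurcation: add this branch onto the child
                lab, bl = parts[0].rsplit(":", 1)
                return f"{lab}:{float(bl) + float(self.blen[v])!r}"
            bl = float(self.blen[v]) if v != self.root else 0.0
            return f"({','.join(parts)}):{bl!r}"
        body = render(self.root)
        if body is None:
            raise ValueError("pruning removed every tip")
        if ":" in body and not body.startswith("("):
            body = f"({body})"
        return read_newick(body + ";")

    def __eq__(self, other: object) -> bool:  # topology + lengths + labels
        if not isinstance(other, Phylogeny):
            return NotImplemented
        return _canonical(self) == _canonical(other)


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _canonical(tree: Phylogeny) -> str:
    def rec(v: int) -> str:
        if v < tree.n_tips:
            return f"{tree.tip_labels[v]}:{tree.blen[v]:.10g}"
        parts = sorted(rec(c) for c in tree.children[v])
        bl = tree.blen[v] if v != tree.root else 0.0
        return f"({','.join(parts)}):{bl:.10g}"
    return rec(tree.root)


# -- Newick I/O ----------------------------------------------------------

def read_newick(text: str, collapse_zero: bool = False) -> Phylogeny:
    """Parse a Newick string (branch lengths required on all non-root edges).

    ``collapse_zero`` merges zero-length internal branches into their parent
    instead of rejecting the tree.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    root = dtree.seed_node
    # collect nodes; tips in traversal (newick) order
    tips = [nd for nd in dtree.preorder_node_iter() if nd.is_leaf()]
    internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    for nd in tips + internals:
        if nd is not root and nd.edge.length is None:
            raise TreeParseError("missing branch length on an edge")
    if collapse_zero:
        for nd in list(dtree.preorder_node_iter()):
            if nd is not root and not nd.is_leaf() and nd.edge.length == 0:
                parent = nd.parent_node
                for ch in list(nd.child_nodes()):
                    nd.remove_child(ch)
                    parent.add_child(ch)
                parent.remove_child(nd)
        tips = [nd for nd in dtree.preorder_node_iter() if nd.is_leaf()]
        internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    index = {nd: i for i, nd in enumerate(tips)}
    index.update({nd: len(tips) + i for i, nd in enumerate(internals)})
    n = len(index)
    parent = np.full(n, -1, dtype=int)
    blen = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    labels = []
    for nd, i in index.items():
        if nd.is_leaf():
            labels.append((i, nd.taxon.label if nd.taxon else ""))
        if nd is not root:
            parent[i] = index[nd.parent_node]
            blen[i] = float(nd.edge.length)
            children[index[nd.parent_node]].append(i)
    labels.sort()
    tip_labels = [lab for _, lab in labels]
    if any(not lab for lab in tip_labels):
        raise TreeParseError("unlabelled tip in Newick string")
    return Phylogeny(parent=parent, blen=blen, tip_labels=tip_labels, children=children)


def write_newick(tree: Phylogeny) -> str:
    def rec(v: int) -> str:
        if v < tree.n_tips:
            return f"{_quote(tree.tip_labels[v])}:{tree.blen[v]:.12g}"
        inner = ",".join(rec(c) for c in tree.children[v])
        if v == tree.root:
            return f"({inner})"
        return f"({inner}):{tree.blen[v]:.12g}"
    return rec(tree.root) + ";"


# -- covariance structure ------------------------------------------------

def vcv(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion covariance: C[i, j] = root-to-MRCA(i, j) path length,
    diagonal = root-to-tip depths. Rows/columns follow ``tree.tip_labels``."""
    n = tree.n_tips
    C = np.zeros((n, n))
    depths = tree.depths()
    tipsets: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if v < n:
            tipsets[v] = np.array([v])
            C[v, v] = depths[v]
        else:
            kids = [tipsets.pop(c) for c in tree.children[v]]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia, ib = np.ix_(kids[a], kids[b])
                    C[ia, ib] = depths[v]
                    C[ib, ia] = depths[v]
            tipsets[v] = np.concatenate(kids)
    return C


def lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: off-diagonal shared history scaled by lam in [0, 1]."""
    if not 0.0 <= lam <= 1.0 + 1e-8:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    lam = min(lam, 1.0)
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def ou_cov(C: np.ndarray, alpha: float, tree_height: float) -> np.ndarray:
    """Fixed-root OU covariance on an ultrametric tree of height T:
    V_ij = exp(-2 a (T - t_ij)) (1 - exp(-2 a t_ij)) / (2 a), t_ij = C_ij.
    Multiply by sigma^2 downstream."""
    if alpha <= 0:
        raise ValueError("OU attraction alpha must be > 0")
    T = tree_height
    if not np.allclose(np.diag(C), T, rtol=1e-6):
        raise ValueError("OU transform requires an ultrametric tree (equal tip depths)")
    return np.exp(-2.0 * alpha * (T - C)) * (1.0 - np.exp(-2.0 * alpha * C)) / (2.0 * alpha)


def eb_cov(C: np.ndarray, a: float) -> np.ndarray:
    """Early-burst: rates decay as exp(a t), a <= 0; entrywise
    (exp(a t_ij) - 1)/a with the a -> 0 limit t_ij."""
    if a > 0:
        raise ValueError("EB exponent a must be <= 0")
    if a == 0 or abs(a) < 1e-300:
        return C.copy()
    return np.expm1(a * C) / a


def transform_covariance(
    C: np.ndarray, model: str, params: dict, tree_height: float | None = None
) -> np.ndarray:
    """Dispatch: model in {'BM', 'lambda', 'OU', 'EB'} (case-insensitive;
    'OU_fixed_root' accepted). BM returns C unchanged."""
    m = model.lower()
    if m == "bm":
        return C.copy()
    if m == "lambda":
        return lambda_cov(C, params["lambda"])
    if m in ("ou", "ou_fixed_root"):
        if tree_height is None:
            tree_height = float(np.max(np.diag(C)))
        return ou_cov(C, params["alpha"], tree_height)
    if m == "eb":
        return eb_cov(C, params["a"])
    raise ValueError(f"unknown covariance model {model!r}")


def rescale_lambda(tree: Phylogeny, lam: float) -> Phylogeny:
    """Tree whose BM covariance equals the lambda transform of ``tree``'s:
    every branch is scaled by lam and each terminal branch is extended by
    (1 - lam) x tip depth, preserving tip variances."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    depths = tree.depths()
    # tiny floor keeps lam=0 representable (internal branches would collapse)
    blen = np.maximum(tree.blen * lam, 1e-12 * max(tree.tree_height, 1.0))
    blen[tree.root] = 0.0
    for i in range(tree.n_tips):
        blen[i] = tree.blen[i] * lam + (1.0 - lam) * depths[i]
    out = Phylogeny(parent=tree.parent.copy(), blen=blen,
                    tip_labels=list(tree.tip_labels),
                    children=[list(c) for c in tree.children])
    return out
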