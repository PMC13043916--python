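"""Phylogeny container, newick I/O, and phylogenetic covariance machinery.

A :class:`Phylogeny` is a rooted tree with branch lengths stored as flat
parent/length arrays in preorder.  All downstream covariance structure used by
the regressions and trait-evolution models derives from it: the Brownian
variance-covariance matrix (shared root-to-MRCA path lengths) and its
transformations under Pagel's lambda, Ornstein-Uhlenbeck, early-burst and
white-noise models.

Newick reading and writing is delegated to dendropy; pruning and covariance
construction are implemented directly on the array representation so that tip
order, unary-node collapsing and path-length bookkeeping are fully explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "StructureParams",
    "parse_newick",
    "read_newick_file",
    "read_posterior_trees",
    "write_newick",
    "write_posterior_trees",
    "prune_to_taxa",
    "vcv_matrix",
    "transform_structure",
]

_PSD_RTOL = 1e-10


class NewickError(ValueError):
    """Malformed or incomplete newick input."""


@dataclass
class Phylogeny:
    """Rooted phylogeny with branch lengths, nodes in preorder (root first).

    Parameters
    ----------
    parent
        ``parent[i]`` is the preorder index of node *i*'s parent; ``-1`` for
        the root (node 0).
    length
        Branch length of the edge above each node; ``length[0]`` is 0 unless
        the input newick carried a root edge.
    label
        Node labels; every tip must carry a unique, non-empty label.
    """

    parent: np.ndarray
    length: np.ndarray
    label: list

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.length = np.asarray(self.length, dtype=float)
        if np.any(self.length < 0):
            bad = int(np.argmin(self.length))
            raise NewickError(
                f"negative branch length {self.length[bad]} above node "
                f"{self.label[bad] or bad}"
            )
        n_nodes = len(self.parent)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for i in range(1, n_nodes):
            children[self.parent[i]].append(i)
        self._children = children
        self._tip_idx = np.array(
            [i for i in range(n_nodes) if not children[i]], dtype=int
        )
        tips = [self.label[i] for i in self._tip_idx]
        if any(not t for t in tips):
            raise NewickError("every tip must carry a label")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        # depth below the top of the root edge: a nonzero root edge
        # (arising from pruning away one side of the root) is shared by
        # every tip and enters all covariances
        depth = np.zeros(n_nodes)
        depth[0] = self.length[0]
        for i in range(1, n_nodes):
            depth[i] = depth[self.parent[i]] + self.length[i]
        self._depth = depth

    # ------------------------------------------------------------------ #
    @property
    def n_tips(self) -> int:
        return len(self._tip_idx)

    @property
    def tips(self) -> list[str]:
        """Tip labels in preorder traversal order."""
        return [self.label[i] for i in self._tip_idx]

    @property
    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path length per tip, in ``tips`` order."""
        return self._depth[self._tip_idx].copy()

    @property
    def node_depths(self) -> np.ndarray:
        return self._depth.copy()

    @property
    def root_height(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self._depth[self._tip_idx].max())

    def children(self, node: int) -> list:
        return list(self._children[node])

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self._depth[self._tip_idx]
        return bool(np.ptp(d) <= rtol * max(d.max(), 1e-300))

    # ------------------------------------------------------------------ #
    def tip_mask_below(self) -> np.ndarray:
        """Boolean matrix ``M[node, tip]``: tip descends from (or is) node.

        Rows are all nodes in preorder; columns follow ``tips`` order.  Row 0
        (the root) is all-True.  The rows for non-root nodes describe each
        edge of the tree: the BM covariance is ``M[1:].T @ diag(length[1:]) @
        M[1:]``, which is the machinery the variable-rates sampler uses to
        rebuild covariances from per-branch rate scalars.
        """
        n_nodes, n = self.n_nodes, self.n_tips
        col = {t: j for j, t in enumerate(self._tip_idx)}
        M = np.zeros((n_nodes, n), dtype=bool)
        for i in range(n_nodes - 1, -1, -1):
            if not self._children[i]:
                M[i, col[i]] = True
            else:
                for c in self._children[i]:
                    M[i] |= M[c]
        return M

    def mrca(self, taxa: Iterable[str]) -> int:
        """Preorder index of the most recent common ancestor of ``taxa``."""
        want = set(taxa)
        missing = want - set(self.tips)
        if missing:
            raise KeyError(f"taxa not on tree: {sorted(missing)}")
        M = self.tip_mask_below()
        cols = [self.tips.index(t) for t in want]
        covering = [i for i in range(self.n_nodes) if M[i, cols].all()]
        return max(covering)  # deepest preorder index covering all = MRCA

    def clade_tips(self, node: int) -> list:
        M = self.tip_mask_below()
        return [t for t, m in zip(self.tips, M[node]) if m]

    # ------------------------------------------------------------------ #
    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, height={self.root_height:.4g})"


@dataclass
class PhyloCovariance:
    """Ordered taxa plus the symmetric PSD matrix of shared path lengths."""

    taxa: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("covariance matrix is not symmetric")
        ev_min = float(np.linalg.eigvalsh(self.matrix).min())
        if ev_min < -_PSD_RTOL * max(np.trace(self.matrix), 1.0):
            raise ValueError(f"covariance not PSD (min eigenvalue {ev_min:g})")

    def subset(self, taxa: Sequence[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(list(taxa), self.matrix[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class StructureParams:
    """Parameters of one correlation/evolution structure.

    ``kind`` selects which fields are read: ``lambda`` uses ``lam``; ``OU``
    uses ``alpha``; ``EB`` uses ``r_eb``; ``trend`` uses ``mu_trend`` (mean
    only — its covariance is Brownian); ``BM``/``white`` use only ``sigma2``.
    """

    kind: str
    lam: float = 1.0
    alpha: float = 1.0
    r_eb: float = 0.0
    mu_trend: float = 0.0
    sigma2: float = 1.0

    KINDS = ("BM", "lambda", "OU", "EB", "trend", "white")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if self.kind == "lambda" and not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        if self.kind == "OU" and self.alpha <= 0:
            raise ValueError(f"OU alpha must be > 0, got {self.alpha}")
        if self.kind == "EB" and self.r_eb > 0:
            raise ValueError(f"EB decay must be <= 0, got {self.r_eb}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    @property
    def n_free(self) -> int:
        """Free covariance parameters beyond sigma2 (for AIC bookkeeping)."""
        return {"BM": 0, "white": 0, "lambda": 1, "OU": 1, "EB": 1, "trend": 1}[
            self.kind
        ]


# ---------------------------------------------------------------------- #
# newick I/O (dendropy-backed)
# ---------------------------------------------------------------------- #

def _from_dendropy(dtree: "dendropy.Tree") -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.empty(len(nodes), dtype=int)
    length = np.zeros(len(nodes))
    labels: list[str] = []
    for i, nd in enumerate(nodes):
        parent[i] = -1 if nd.parent_node is None else index[id(nd.parent_node)]
        if nd.parent_node is not None:
            if nd.edge.length is None:
                who = nd.taxon.label if nd.taxon else f"internal node {i}"
                raise NewickError(f"missing branch length above {who}")
            length[i] = nd.edge.length
        if nd.taxon is not None:
            labels.append(nd.taxon.label)
        elif nd.label is not None:
            labels.append(nd.label)
        else:
            labels.append("")
    tree = Phylogeny(parent, length, labels)
    for i in range(tree.n_nodes):
        if tree._children[i] and len(tree._children[i]) < 2 and i != 0:
            raise NewickError(f"internal node {i} has a single child")
    return tree


def parse_newick(text: str) -> Phylogeny:
    """Parse one newick string into a :class:`Phylogeny`.

    Every edge must carry a branch length; a missing length is an error, not
    a silent zero.  Malformed input raises :class:`NewickError` carrying the
    tokenizer's position information.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several tokenizer subclasses
        raise NewickError(f"newick parse error: {exc}") from exc
    if dtree.seed_node is None or (
        not dtree.seed_node.child_nodes() and dtree.seed_node.taxon is None
    ):
        raise NewickError("empty newick string")
    return _from_dendropy(dtree)


def write_newick(tree: Phylogeny, precision: int = 12) -> str:
    parts: list[str] = [""] * tree.n_nodes
    for i in range(tree.n_nodes - 1, -1, -1):
        kids = tree._children[i]
        if kids:
            inner = ",".join(parts[c] for c in kids)
            core = f"({inner})"
        else:
            core = tree.label[i]
        if i == 0:
            parts[i] = core + ";"
        else:
            parts[i] = f"{core}:{tree.length[i]:.{precision}g}"
    return parts[0]


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_posterior_trees(path) -> list:
    """Read a multi-newick file (one tree per line) into a list of trees."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_posterior_trees(trees: Iterable[Phylogeny], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------- #
# pruning
# ---------------------------------------------------------------------- #

def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict the tree to ``keep``, collapsing unary nodes.

    Path lengths between retained tips are preserved exactly: when an
    internal node is left with a single child its two incident branch
    lengths are summed.
    """
    keep = set(keep)
    missing = keep - set(tree.tips)
    if missing:
        raise KeyError(f"taxa not on tree: {sorted(missing)}")
    if len(keep) < 1:
        raise ValueError("keep must name at least one tip")

    n = tree.n_nodes
    retained = np.zeros(n, dtype=bool)
    for i in tree._tip_idx:
        if tree.label[i] in keep:
            retained[i] = True
    for i in range(n - 1, 0, -1):
        if retained[i]:
            retained[tree.parent[i]] = True

    # new children lists restricted to retained nodes
    new_parent: dict[int, int] = {}
    new_length: dict[int, float] = {}
    for i in range(1, n):
        if retained[i]:
            new_parent[i] = tree.parent[i]
            new_length[i] = float(tree.length[i])

    def kept_children(i: int) -> list:
        return [c for c in tree._children[i] if retained[c]]

    # collapse unary chains (root handled after)
    order = [i for i in range(n) if retained[i]]
    for i in order:
        if i == 0:
            continue
        kids = [c for c, p in new_parent.items() if p == i]
        if len(kids) == 1 and not (not tree._children[i] and tree.label[i] in keep):
            (c,) = kids
            new_length[c] += new_length[i]
            new_parent[c] = new_parent[i]
            del new_parent[i], new_length[i]

    # find new root: walk down from the old root through any unary chain,
    # accumulating the traversed lengths as the new root's root edge so
    # covariances are preserved exactly under subsetting
    root = 0
    stem = float(tree.length[0])
    while True:
        kids = [c for c, p in new_parent.items() if p == root]
        if len(kids) == 1 and (root == 0 or root not in new_length):
            nxt = kids[0]
            stem += new_length[nxt]
            del new_parent[nxt], new_length[nxt]
            root = nxt
            continue
        break

    # reindex in preorder
    children_map: dict[int, list] = {}
    for c, p in new_parent.items():
        children_map.setdefault(p, []).append(c)
    for v in children_map.values():
        v.sort()
    order2: list[int] = []
    stack = [root]
    while stack:
        nd = stack.pop()
        order2.append(nd)
        stack.extend(reversed(children_map.get(nd, [])))
    remap = {old: new for new, old in enumerate(order2)}
    parent_arr = np.array(
        [-1] + [remap[new_parent[o]] for o in order2[1:]], dtype=int
    )
    length_arr = np.array([stem] + [new_length[o] for o in order2[1:]])
    labels = [tree.label[o] for o in order2]
    return Phylogeny(parent_arr, length_arr, labels)


# ---------------------------------------------------------------------- #
# covariance construction and transforms
# ---------------------------------------------------------------------- #

def vcv_matrix(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion variance-covariance matrix of the tree.

    Entry (i, j) is the root-to-MRCA path length shared by tips i and j;
    the diagonal holds root-to-tip distances.
    """
    if tree.n_tips < 2:
        raise ValueError("covariance needs at least 2 tips")
    M = tree.tip_mask_below()[1:].astype(float)  # edges x tips
    w = tree.length[1:]
    V = (M * w[:, None]).T @ M
    V += tree.length[0]  # root edge, shared by every pair of tips
    return PhyloCovariance(tree.tips, V)


def transform_structure(
    C: PhyloCovariance, tree: Phylogeny, p: StructureParams
) -> PhyloCovariance:
    """Transform a BM covariance under one evolutionary structure.

    lambda multiplies off-diagonals by ``lam``; OU applies the (possibly
    non-ultrametric) Ornstein-Uhlenbeck covariance
    ``sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij))`` with
    ``d_ij`` the patristic distance and ``t_ij`` the shared depth; EB maps
    shared depths elementwise through ``(exp(r t) - 1)/r``; white is
    ``sigma2 * I``; BM (and trend, whose covariance is Brownian) scale by
    ``sigma2`` only.
    """
    V = C.matrix
    d = np.diag(V)
    if p.kind in ("BM", "trend"):
        out = p.sigma2 * V
    elif p.kind == "lambda":
        out = p.sigma2 * (p.lam * V + (1.0 - p.lam) * np.diag(d))
    elif p.kind == "white":
        out = p.sigma2 * np.eye(len(d))
    elif p.kind == "EB":
        r = p.r_eb
        out = p.sigma2 * (V if r == 0 else (np.expm1(r * V)) / r)
    elif p.kind == "OU":
        a = p.alpha
        patristic = d[:, None] + d[None, :] - 2.0 * V
        out = (
            p.sigma2
            / (2.0 * a)
            * np.exp(-a * patristic)
            * (-np.expm1(-2.0 * a * V))
        )
    else:  # pragma: no cover
        raise AssertionError(p.kind)
    return PhyloCovariance(list(C.taxa), out)
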