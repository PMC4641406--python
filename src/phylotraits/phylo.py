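"""Rooted time trees: parsing, geometry, and pruning.

The container used throughout the package is :class:`Phylogeny`, a compact
array-backed rooted tree with branch lengths in relative time.  The time
axis runs root -> tips: the root sits at height 0 and heights increase
toward the present, so an ultrametric tree has all tips at the tree
height ``T``.

Newick I/O is delegated to :mod:`dendropy`; this module only converts to
and from the array representation and enforces the stricter contracts we
need (every non-root edge must carry a branch length, tip labels must be
unique and non-empty).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import dendropy

__all__ = [
    "Phylogeny",
    "NewickError",
    "read_newick",
    "write_newick",
    "prune_tips",
    "is_ultrametric",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or missing branch lengths."""


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths, nodes indexed 0..n-1 in preorder.

    Attributes
    ----------
    parent : ndarray of int
        ``parent[i]`` is the parent index of node ``i``; the root (index 0)
        has parent ``-1``.
    edge_length : ndarray of float
        Length of the edge *above* each node; ``edge_length[0]`` is 0.
    labels : list of str or None
        Tip label for leaves, internal label if present, else ``None``.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    labels: list
    children: list = field(default=None, repr=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        n = len(self.parent)
        if self.children is None:
            ch = [[] for _ in range(n)]
            for i in range(1, n):
                ch[self.parent[i]].append(i)
            self.children = ch
        self._validate()

    # -- construction-time checks -------------------------------------
    def _validate(self):
        n = self.n_nodes
        if n < 2:
            raise ValueError("a phylogeny needs at least 2 nodes")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValueError("exactly one root (node 0) is required")
        if np.any(self.edge_length[1:] < 0):
            raise ValueError("negative edge length")
        if np.any(self.edge_length[1:] == 0):
            warnings.warn("tree contains zero-length edges", stacklevel=3)
        tips = self.tip_indices
        labs = [self.labels[i] for i in tips]
        if any(not l for l in labs):
            raise ValueError("every tip needs a non-empty label")
        if len(set(labs)) != len(labs):
            dup = sorted({l for l in labs if labs.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        if self.height.max() <= 0:
            raise ValueError("total tree height must be positive")

    # -- basic geometry ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self.children[i]],
                        dtype=np.int64)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def height(self) -> np.ndarray:
        """Height of every node above the root (root = 0)."""
        h = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):  # preorder: parent precedes child
            h[i] = h[self.parent[i]] + self.edge_length[i]
        return h

    @property
    def tree_height(self) -> float:
        return float(self.height.max())

    def tip_index(self, label: str) -> int:
        for i in self.tip_indices:
            if self.labels[i] == label:
                return int(i)
        raise KeyError(label)

    def postorder(self) -> np.ndarray:
        return np.arange(self.n_nodes - 1, -1, -1, dtype=np.int64)

    def preorder(self) -> np.ndarray:
        return np.arange(self.n_nodes, dtype=np.int64)

    def mrca(self, i: int, j: int) -> int:
        """Most recent common ancestor of two node indices."""
        anc = set()
        a = i
        while a != -1:
            anc.add(a)
            a = int(self.parent[a]) if a != 0 else -1
        b = j
        while b not in anc:
            b = int(self.parent[b])
        return int(b)

    def mrca_matrix(self, nodes=None) -> np.ndarray:
        """Pairwise MRCA indices for a set of nodes (default: tips).

        The all-tips matrix is cached on first use (it is the hot input
        of every covariance construction)."""
        if nodes is None:
            cached = getattr(self, "_tip_mrca", None)
            if cached is not None:
                return cached
            m = self._tip_mrca_matrix()
            object.__setattr__(self, "_tip_mrca", m)
            return m
        k = len(nodes)
        chains = []
        for u in nodes:
            c = []
            a = int(u)
            while a != -1:
                c.append(a)
                a = int(self.parent[a]) if a != 0 else -1
            chains.append(set(c))
        out = np.empty((k, k), dtype=np.int64)
        for a in range(k):
            out[a, a] = nodes[a]
            for b in range(a + 1, k):
                x = int(nodes[a])
                while x not in chains[b]:
                    x = int(self.parent[x])
                out[a, b] = out[b, a] = x
        return out

    def _tip_mrca_matrix(self) -> np.ndarray:
        """All-tips MRCA matrix: for each internal node, tip pairs drawn
        from two different child subtrees have that node as MRCA."""
        tips = self.tip_indices
        pos = {int(t): k for k, t in enumerate(tips)}
        out = np.empty((len(tips), len(tips)), dtype=np.int64)
        below = [None] * self.n_nodes
        for i in self.postorder():
            ch = self.children[i]
            if not ch:
                out[pos[i], pos[i]] = i
                below[i] = np.array([pos[i]], dtype=np.int64)
                continue
            sets = [below[c] for c in ch]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    out[np.ix_(sets[a], sets[b])] = i
                    out[np.ix_(sets[b], sets[a])] = i
            below[i] = np.concatenate(sets)
        return out

    def patristic_matrix(self) -> np.ndarray:
        """Pairwise path-length distances between tips (tip order)."""
        h = self.height
        tips = self.tip_indices
        m = self.mrca_matrix()
        hi = h[tips][:, None]
        return hi + hi.T - 2.0 * h[m]

    def summary(self) -> dict:
        return {
            "n_tips": int(self.n_tips),
            "height": self.tree_height,
            "ultrametric": bool(is_ultrametric(self)),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary())

    def __eq__(self, other):
        return (isinstance(other, Phylogeny)
                and np.array_equal(self.parent, other.parent)
                and np.allclose(self.edge_length, other.edge_length)
                and self.labels == other.labels)


# ---------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.empty(len(nodes), dtype=np.int64)
    elen = np.zeros(len(nodes))
    labels = []
    for i, nd in enumerate(nodes):
        parent[i] = -1 if nd.parent_node is None else index[id(nd.parent_node)]
        if nd.parent_node is not None:
            if nd.edge.length is None:
                who = nd.taxon.label if nd.taxon else (nd.label or f"node {i}")
                raise NewickError(
                    f"missing branch length on edge above '{who}'; "
                    "branch lengths are required on all non-root edges")
            elen[i] = float(nd.edge.length)
        lab = nd.taxon.label if nd.taxon is not None else nd.label
        labels.append(lab)
    return Phylogeny(parent, elen, labels)


def read_newick(text: str) -> Phylogeny:
    """Parse one Newick tree string into a :class:`Phylogeny`.

    Branch lengths are mandatory on every non-root edge.  Quoted labels
    are supported; NHX/figtree comments are dropped with a warning.
    """
    if "[" in text:
        warnings.warn("bracket comments in Newick input are ignored",
                      stacklevel=2)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as e:  # dendropy raises several error classes
        pos = ""
        col = getattr(e, "column", None) or getattr(e, "column_num", None)
        if col is not None:
            pos = f" near character {col}"
        raise NewickError(f"malformed Newick{pos}: {e}") from None
    if len(dtree.leaf_nodes()) < 2:
        raise NewickError("tree has fewer than 2 tips")
    return _from_dendropy(dtree)


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick with 17-significant-digit branch lengths."""
    def fmt(i):
        if tree.children[i]:
            inner = ",".join(fmt(c) for c in tree.children[i])
            lab = tree.labels[i] or ""
            s = f"({inner}){_quote(lab)}"
        else:
            s = _quote(tree.labels[i])
        if i != 0:
            s += f":{tree.edge_length[i]:.17g}"
        return s
    return fmt(0) + ";"


def _quote(label):
    if not label:
        return ""
    if any(c in label for c in "(),:;[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------
# Tree surgery and predicates
# ---------------------------------------------------------------------

def prune_tips(tree: Phylogeny, keep) -> Phylogeny:
    """Induced subtree on a subset of tip labels.

    Degree-2 internal nodes created by the pruning are collapsed with
    their edge lengths summed, so tip heights (and hence all patristic
    distances among kept tips) are preserved.
    """
    keep = set(keep)
    have = set(tree.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise KeyError(f"tip labels not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("keep at least 2 tips")

    # mark retained nodes: kept tips and all their ancestors
    retain = np.zeros(tree.n_nodes, dtype=bool)
    for i in tree.tip_indices:
        if tree.labels[i] in keep:
            a = int(i)
            while a != -1 and not retain[a]:
                retain[a] = True
                a = int(tree.parent[a]) if a != 0 else -1

    kept_children = [[c for c in tree.children[i] if retain[c]]
                     for i in range(tree.n_nodes)]

    # walk down from the old root, skipping degree-2 chains
    def effective_root(i):
        while len(kept_children[i]) == 1:
            i = kept_children[i][0]
        return i

    new_parent, new_elen, new_labels = [], [], []

    def build(i, parent_idx, extra_len):
        ch = kept_children[i]
        while len(ch) == 1:  # collapse pass-through node
            extra_len += tree.edge_length[ch[0]]
            i, ch = ch[0], kept_children[ch[0]]
        idx = len(new_parent)
        new_parent.append(parent_idx)
        new_elen.append(extra_len)
        new_labels.append(tree.labels[i])
        for c in ch:
            build(c, idx, tree.edge_length[c])

    root = effective_root(0)
    build(root, -1, 0.0)
    new_elen[0] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-length warnings already issued
        return Phylogeny(np.array(new_parent), np.array(new_elen), new_labels)


def is_ultrametric(tree: Phylogeny, tol: float = 1e-9) -> bool:
    """True iff all tip heights agree within ``tol`` x tree height."""
    h = tree.height[tree.tip_indices]
    return bool(h.max() - h.min() <= tol * max(h.max(), np.finfo(float).tiny))
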