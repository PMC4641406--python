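"""Synthetic data with known truth, plus species-mean PCA.

Morphometric species means and occurrence-derived climate scores are
rarely deposited in machine-readable form, so every test surface in
this package runs on synthetic data: Yule trees and trait values
simulated under each implemented model with recorded true parameters.
All generators are pure functions of (parameters, seed).

``pca_species_means`` is the small data-prep utility that turns a table
of per-species trait means into orthogonal PC axes (covariance-matrix
PCA of untransformed means), the form in which continuous traits enter
the evolutionary models.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .phylo import Phylogeny, write_newick
from .regimes import RegimeMap, shift_branches_to_era_map
from .models import TraitData, ModelSpec
from .simulate import simulate_realization

__all__ = ["SyntheticDataset", "OrdinationResult", "yule_tree",
           "make_recovery_dataset", "pca_species_means"]


def yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0,
              scale_height: float = 1.0) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree.

    Lineages split at rate ``birth_rate``; the process runs until
    ``n_tips`` lineages exist plus one final exponential waiting time so
    terminal branches have positive length.  By default heights are
    rescaled so the tree height is ``scale_height`` (pass ``None`` to
    keep raw Yule time, e.g. for rate-calibration checks).
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(int(seed))
    # crown process: the root splits at time 0 into two lineages
    parent = [-1, 0, 0]
    btime = [0.0, 0.0, 0.0]       # time each node came into existence
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        j = int(rng.integers(len(active)))
        node = active[j]
        for _ in range(2):
            parent.append(node)
            btime.append(t)
        active[j] = len(parent) - 2
        active.append(len(parent) - 1)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    end_time = t

    n = len(parent)
    is_tip = np.ones(n, dtype=bool)
    for i in range(1, n):
        is_tip[parent[i]] = False
    # a node's height: tips end at end_time; an internal node sits at
    # the birth time of its children (the moment it split)
    node_time = np.full(n, end_time)
    node_time[0] = 0.0
    for i in range(1, n):
        if not is_tip[i]:
            node_time[i] = btime[[c for c in range(1, n)
                                  if parent[c] == i][0]]
    # assemble in preorder
    children = [[] for _ in range(n)]
    for i in range(1, n):
        children[parent[i]].append(i)
    order = []
    stack = [0]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(reversed(children[u]))
    newidx = {old: k for k, old in enumerate(order)}
    new_parent = np.array([-1] + [newidx[parent[old]] for old in order[1:]])
    new_time = np.array([node_time[old] for old in order])
    elen = np.zeros(n)
    for k in range(1, n):
        elen[k] = new_time[k] - new_time[new_parent[k]]
    if scale_height is not None:
        elen *= scale_height / end_time
    labels = []
    tip_no = 1
    for old in order:
        if is_tip[old]:
            labels.append(f"t{tip_no}")
            tip_no += 1
        else:
            labels.append(None)
    return Phylogeny(new_parent, elen, labels)


@dataclass
class SyntheticDataset:
    """A tree, painting, true model, and traits simulated under it."""

    tree: Phylogeny
    painting: RegimeMap
    spec: ModelSpec
    data: TraitData
    seed: int
    shift_edges: tuple = ()

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(write_newick(self.tree).encode())
        for l in sorted(self.data.values):
            h.update(f"{l}={self.data.values[l]:.12g};".encode())
        return h.hexdigest()[:16]


def _clade_sizes(tree: Phylogeny) -> np.ndarray:
    sz = np.zeros(tree.n_nodes, dtype=np.int64)
    for i in tree.postorder():
        if not tree.children[i]:
            sz[i] = 1
        else:
            sz[i] = sum(sz[c] for c in tree.children[i])
    return sz


def pick_clade_edge(tree: Phylogeny, frac_lo: float = 0.2,
                    frac_hi: float = 0.4) -> int:
    """Largest non-root clade holding between frac_lo and frac_hi of the
    tips; the conventional location for a planted rate/regime shift."""
    n = tree.n_tips
    sz = _clade_sizes(tree)
    cand = [i for i in range(1, tree.n_nodes)
            if frac_lo * n <= sz[i] <= frac_hi * n]
    if not cand:
        raise ValueError(f"no clade with {frac_lo:.0%}-{frac_hi:.0%} of tips")
    return max(cand, key=lambda i: (sz[i], -i))


def make_recovery_dataset(family: str, params: dict, n_tips: int,
                          painting_rule: str = None,
                          seed: int = 0) -> SyntheticDataset:
    """Tree + painting + traits simulated under known parameters.

    ``painting_rule``: None (single regime "0") or "clade_shift" (one
    shift on the largest clade holding 20-40% of the tips; regimes
    "0" outside, the shift-node label inside).  ``params`` supplies the
    ModelSpec fields (sigma2, alpha, theta, r, x0) with dict-valued
    entries keyed "0"/"1" remapped onto the actual painting labels.
    """
    tree = yule_tree(n_tips, seed=seed)
    if painting_rule is None:
        painting = RegimeMap.single(tree, "0")
        shift_edges = ()
        label_map = {"0": "0"}
    elif painting_rule == "clade_shift":
        e = pick_clade_edge(tree)
        painting = shift_branches_to_era_map(tree, [e])
        shift_edges = (e,)
        label_map = {"0": "0", "1": str(e)}
    else:
        raise ValueError(f"unknown painting rule {painting_rule!r}")

    def remap(v):
        if isinstance(v, dict):
            return {label_map[k]: float(x) for k, x in v.items()}
        return v

    spec = ModelSpec(family,
                     sigma2=remap(params["sigma2"]),
                     alpha=remap(params.get("alpha")),
                     theta=remap(params.get("theta")),
                     r=params.get("r", 0.0),
                     x0=params.get("x0"))
    rng = np.random.default_rng([int(seed), 2 ** 20])
    _, _, _, x0 = spec.resolve(painting)
    real = simulate_realization(tree, painting, spec, x0, rng)
    tips = tree.tip_indices
    data = TraitData({tree.labels[i]: float(real.nodes[i]) for i in tips})
    return SyntheticDataset(tree=tree, painting=painting, spec=spec,
                            data=data, seed=int(seed),
                            shift_edges=shift_edges)


# ---------------------------------------------------------------------
# Covariance-matrix PCA of species means
# ---------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """PCA of a species x variables table of trait means."""

    species: list
    variables: list
    scores: np.ndarray           # (n_species, n_axes)
    loadings: np.ndarray         # (n_variables, n_axes), orthonormal cols
    variance_fraction: np.ndarray
    eigenvalues: np.ndarray

    def scores_tsv(self) -> str:
        hdr = "species\t" + "\t".join(f"PC{j+1}"
                                      for j in range(self.scores.shape[1]))
        lines = [hdr]
        for s, row in zip(self.species, self.scores):
            lines.append(s + "\t" + "\t".join(f"{v:.8g}" for v in row))
        return "\n".join(lines) + "\n"


def pca_species_means(table, species=None, variables=None) -> OrdinationResult:
    """Covariance-matrix PCA of untransformed species means.

    ``table``: (n_species, n_variables) array-like, or a pandas
    DataFrame (index = species).  Scores are the centered data projected
    on the covariance eigenvectors; per-axis variance fraction is
    eigenvalue / trace.  Sign convention: each loading vector's
    largest-magnitude entry is positive (axis polarity is arbitrary).
    """
    try:
        import pandas as pd
        if isinstance(table, pd.DataFrame):
            species = list(table.index.astype(str))
            variables = list(table.columns.astype(str))
            table = table.to_numpy(dtype=float)
    except ImportError:       # pandas is a hard dependency, but be safe
        pass
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 species and >= 2 variables")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite cells")
    ns, nv = X.shape
    species = species or [f"sp{i+1}" for i in range(ns)]
    variables = variables or [f"v{j+1}" for j in range(nv)]
    Xc = X - X.mean(axis=0)
    C = np.cov(Xc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(nv):                       # deterministic polarity
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Xc @ evecs
    tr = evals.sum()
    if tr == 0:
        raise ValueError("all variables constant")
    return OrdinationResult(species=species, variables=variables,
                            scores=scores, loadings=evecs,
                            variance_fraction=evals / tr,
                            eigenvalues=evals)
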