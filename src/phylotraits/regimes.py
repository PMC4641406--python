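"""Selective regimes: 2-state Markov fitting and branch paintings.

A *painting* (:class:`RegimeMap`) assigns a piecewise-constant regime
label along every edge of the tree; multi-regime OU and multi-rate BM
models consume it.  Paintings are built either from discrete node states
(each edge takes its child's state) or from a set of "shift" edges that
open a new rate class for the whole descendant clade (era style).

The 2-state Mk machinery (ER or ARD rates, pruning likelihood, marginal
ancestral states) is what turns binary tip data -- pollination syndrome,
geographic distribution -- into a regime painting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .phylo import Phylogeny

__all__ = [
    "RegimeMap", "MkFit", "fit_mk2",
    "states_to_regime_map", "shift_branches_to_era_map",
]

_COVER_TOL = 1e-9


@dataclass
class RegimeMap:
    """Piecewise-constant regime labels along every edge.

    ``segments[i]`` is the ordered (parent-end first) list of
    ``(duration, label)`` pairs covering the edge above node ``i``; the
    root (no edge) has an empty list.  ``root_label`` is the regime in
    force at the root itself.
    """

    tree: Phylogeny
    segments: list
    root_label: str = None

    def __post_init__(self):
        t = self.tree
        if len(self.segments) != t.n_nodes:
            raise ValueError("one segment list per node required")
        for i in range(1, t.n_nodes):
            segs = self.segments[i]
            if not segs:
                raise ValueError(f"edge above node {i} has no segments")
            tot = sum(d for d, _ in segs)
            if abs(tot - t.edge_length[i]) > _COVER_TOL * max(1.0, t.edge_length[i]):
                raise ValueError(
                    f"segments on edge above node {i} sum to {tot}, "
                    f"edge length is {t.edge_length[i]}")
            if any(d <= 0 for d, _ in segs):
                raise ValueError(f"non-positive segment duration on edge {i}")
            for (_, a), (_, b) in zip(segs, segs[1:]):
                if a == b:
                    raise ValueError("adjacent segments share a label")
        if self.root_label is None:
            # regime in force where the root's first child edge begins
            for c in t.children[0]:
                self.root_label = self.segments[c][0][1]
                break

    @property
    def labels(self) -> list:
        out = {self.root_label}
        for segs in self.segments[1:]:
            out.update(lab for _, lab in segs)
        return sorted(out)

    def duration_by_regime(self) -> dict:
        tot = {}
        for segs in self.segments[1:]:
            for d, lab in segs:
                tot[lab] = tot.get(lab, 0.0) + d
        return tot

    def edge_label(self, i: int) -> str:
        """Label of the (single-segment) edge above node i."""
        segs = self.segments[i]
        if len(segs) != 1:
            raise ValueError(f"edge above node {i} has {len(segs)} segments")
        return segs[0][1]

    @classmethod
    def single(cls, tree: Phylogeny, label: str = "0") -> "RegimeMap":
        segs = [[] if i == 0 else [(float(tree.edge_length[i]), label)]
                for i in range(tree.n_nodes)]
        # zero-length edges get a token epsilon-free single segment:
        # coverage demands duration == edge length, so keep exact value
        for i in range(1, tree.n_nodes):
            if tree.edge_length[i] == 0:
                segs[i] = [(0.0, label)]
        return cls._build(tree, segs, label)

    @classmethod
    def _build(cls, tree, segs, root_label):
        obj = cls.__new__(cls)
        obj.tree, obj.segments, obj.root_label = tree, segs, root_label
        return obj

    def to_tsv(self) -> str:
        h = self.tree.height
        lines = ["child_node\tsegment_start_height\tsegment_end_height\tregime"]
        for i in range(1, self.tree.n_nodes):
            t0 = h[self.tree.parent[i]]
            for d, lab in self.segments[i]:
                lines.append(f"{i}\t{t0:.10g}\t{t0 + d:.10g}\t{lab}")
                t0 += d
        return "\n".join(lines) + "\n"


def states_to_regime_map(tree: Phylogeny, node_states: dict) -> RegimeMap:
    """Paint each edge uniformly with the state of its *child* node."""
    for i in range(tree.n_nodes):
        if i not in node_states:
            raise KeyError(f"no state for node {i}")
    segs = [[]]
    for i in range(1, tree.n_nodes):
        segs.append([(float(tree.edge_length[i]), str(node_states[i]))])
    return RegimeMap._build(tree, segs, str(node_states[0]))


def shift_branches_to_era_map(tree: Phylogeny, shift_edges) -> RegimeMap:
    """Era-style painting: each shift edge opens a class inherited by the
    whole descendant clade until overridden by a nested shift.

    Classes are labelled "0" for the root class and by the shift edge's
    child-node index otherwise.
    """
    shift_edges = set(int(e) for e in shift_edges)
    bad = [e for e in shift_edges if not (0 < e < tree.n_nodes)]
    if bad:
        raise ValueError(f"not edges of this tree: {bad}")
    cls = ["0"] * tree.n_nodes
    for i in range(1, tree.n_nodes):  # preorder: parent class already set
        cls[i] = str(i) if i in shift_edges else cls[tree.parent[i]]
    segs = [[]]
    for i in range(1, tree.n_nodes):
        segs.append([(float(tree.edge_length[i]), cls[i])])
    return RegimeMap._build(tree, segs, "0")


# ---------------------------------------------------------------------
# Two-state Mk model
# ---------------------------------------------------------------------

@dataclass
class MkFit:
    model: str                   # "ER" | "ARD"
    q01: float
    q10: float
    root_prior: tuple
    loglik: float
    marginals: np.ndarray        # (n_nodes, 2), rows sum to 1
    degenerate: bool = False

    @property
    def rates(self):
        return (self.q01, self.q10)

    def argmax_states(self, tree: Phylogeny) -> dict:
        """Discrete node states from the marginals; ties go to the
        parent's state to keep paintings parsimonious."""
        states = {}
        for i in range(tree.n_nodes):
            p0, p1 = self.marginals[i]
            if abs(p0 - p1) < 1e-12 and i != 0:
                states[i] = states[tree.parent[i]]
            else:
                states[i] = int(p1 > p0)
        return states


def _p_matrix(q01, q10, t):
    """2-state transition probabilities exp(Qt), closed form."""
    s = q01 + q10
    if s <= 0:
        return np.eye(2)
    pi0, pi1 = q10 / s, q01 / s
    e = np.exp(-s * t)
    return np.array([[pi0 + pi1 * e, pi1 * (1 - e)],
                     [pi0 * (1 - e), pi1 + pi0 * e]])


def _mk2_downpass(tree, tip_partials, q01, q10):
    """Felsenstein pruning; returns per-node conditional likelihoods
    L[i, s] of the data below node i given state s, plus log-scalers."""
    n = tree.n_nodes
    L = np.zeros((n, 2))
    logscale = np.zeros(n)
    P = {i: _p_matrix(q01, q10, tree.edge_length[i]) for i in range(1, n)}
    for i in tree.postorder():
        if not tree.children[i]:
            L[i] = tip_partials[i]
            continue
        acc = np.ones(2)
        sc = 0.0
        for c in tree.children[i]:
            acc = acc * (P[c] @ L[c])
            sc += logscale[c]
        m = acc.max()
        if m <= 0:
            raise FloatingPointError("zero likelihood in pruning")
        L[i] = acc / m
        logscale[i] = sc + np.log(m)
    return L, logscale, P


def _mk2_loglik(tree, tip_partials, q01, q10, prior):
    L, logscale, _ = _mk2_downpass(tree, tip_partials, q01, q10)
    return float(np.log(prior @ L[0]) + logscale[0])


def _mk2_marginals(tree, tip_partials, q01, q10, prior):
    """Marginal ancestral probabilities by the outside (re-rooting)
    recursion: marginal(u) ∝ down(u) * out(u)."""
    L, logscale, P = _mk2_downpass(tree, tip_partials, q01, q10)
    n = tree.n_nodes
    out = np.zeros((n, 2))
    out[0] = prior
    for i in range(n):
        for c in tree.children[i]:
            sib = np.ones(2)
            for c2 in tree.children[i]:
                if c2 != c:
                    sib = sib * (P[c2] @ L[c2])
            msg = (out[i] * sib) @ P[c]
            m = msg.max()
            out[c] = msg / m if m > 0 else msg
    marg = out * L
    marg /= marg.sum(axis=1, keepdims=True)
    return marg


def fit_mk2(tree: Phylogeny, tip_states: dict, model: str = "ER",
            root_prior: str = "flat") -> MkFit:
    """ML fit of the 2-state Mk model with marginal ancestral states.

    Parameters
    ----------
    tip_states : dict
        tip label -> state in {0, 1}; every tip must be present.
    model : {"ER", "ARD"}
        Equal rates (one q) or all-rates-different (q01, q10).
    root_prior : {"flat", "stationary"}
        Flat is (1/2, 1/2); stationary uses the rates' equilibrium.
    """
    if model not in ("ER", "ARD"):
        raise ValueError("model must be ER or ARD")
    tips = tree.tip_indices
    missing = [tree.labels[i] for i in tips if tree.labels[i] not in tip_states]
    if missing:
        raise KeyError(f"tips without a state: {missing}")
    tip_partials = {}
    observed = set()
    for i in tips:
        s = int(tip_states[tree.labels[i]])
        if s not in (0, 1):
            raise ValueError("states must be 0 or 1")
        part = np.zeros(2)
        part[s] = 1.0
        tip_partials[int(i)] = part
        observed.add(s)

    T = tree.tree_height
    lo, hi = 1e-8, 100.0 / T
    degenerate = len(observed) == 1
    if degenerate:
        warnings.warn("all tips share one state; Mk rates are driven to "
                      "the lower bound", stacklevel=2)

    def prior_for(q01, q10):
        if root_prior == "stationary":
            s = q01 + q10
            return np.array([q10 / s, q01 / s]) if s > 0 else np.array([.5, .5])
        return np.array([0.5, 0.5])

    def nll(logq):
        q = np.exp(logq)
        q01, q10 = (q[0], q[0]) if model == "ER" else (q[0], q[1])
        return -_mk2_loglik(tree, tip_partials, q01, q10, prior_for(q01, q10))

    ndim = 1 if model == "ER" else 2
    best = None
    for start in np.log([0.5 / T, 2.0 / T, 20.0 / T]):
        x0 = np.full(ndim, start)
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(np.log(lo), np.log(hi))] * ndim)
        if best is None or res.fun < best.fun:
            best = res
    q = np.exp(best.x)
    q01, q10 = (q[0], q[0]) if model == "ER" else (q[0], q[1])
    prior = prior_for(q01, q10)
    marg = _mk2_marginals(tree, tip_partials, q01, q10, prior)
    return MkFit(model=model, q01=float(q01), q10=float(q10),
                 root_prior=tuple(prior), loglik=float(-best.fun),
                 marginals=marg, degenerate=degenerate)


def mk2_loglik_fixed(tree: Phylogeny, tip_states: dict, q01: float,
                     q10: float, root_prior=(0.5, 0.5)) -> float:
    """Pruning log-likelihood at fixed rates (no optimization)."""
    tip_partials = {}
    for i in tree.tip_indices:
        part = np.zeros(2)
        part[int(tip_states[tree.labels[i]])] = 1.0
        tip_partials[int(i)] = part
    return _mk2_loglik(tree, tip_partials, q01, q10, np.asarray(root_prior))
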