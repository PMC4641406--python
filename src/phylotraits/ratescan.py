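"""Reversible-jump MCMC over branch-specific Brownian-motion rates.

The model: an unknown set of "shift" edges partitions the tree into
era-style rate classes (a shift applies to its whole descendant clade
until overridden), each class carrying its own sigma^2.  The sampler
jumps between shift configurations (add / remove / move a shift) and
updates class log-rates, targeting the posterior under

* number of shifts ~ Poisson(lambda) truncated at the number of edges,
* shift locations uniform over edge subsets of that size,
* log sigma^2 per class ~ Normal(log sigma2_hat_BM, prior_sd^2),

with the BM likelihood evaluated by the O(n) pruning recursion and the
root state profiled at its ML value.  Dimension-changing moves draw the
new class rate from its prior, so the prior density cancels in the
acceptance ratio and the Jacobian is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phylo import Phylogeny
from .regimes import RegimeMap, shift_branches_to_era_map
from .models import (TraitData, ModelSpec, FitResult, aicc,
                     bm_pruning_loglik, bm_analytic_mle)
from scipy.optimize import minimize

__all__ = ["RateScanResult", "run_rjmcmc", "map_painting_ml",
           "best_sample_aic", "Priors"]


@dataclass
class Priors:
    """rjMCMC priors; defaults are weakly informative."""

    shift_rate: float = math.log(2.0)   # Poisson mean of #shifts
    log_rate_sd: float = 1.5            # sd of log sigma^2 around BM MLE
    log_rate_mean: float = None         # None -> log sigma2_hat_BM


@dataclass
class Sample:
    shift_edges: tuple       # sorted child-node indices
    log_rates: dict          # class label -> log sigma^2
    loglik: float

    @property
    def n_classes(self) -> int:
        return len(self.shift_edges) + 1

    def painting_hash(self) -> str:
        return ",".join(str(e) for e in self.shift_edges)


@dataclass
class RateScanResult:
    tree: Phylogeny
    shift_prob: np.ndarray        # per node (edge above it); root = 0
    median_rate: np.ndarray       # posterior median relative rate per edge
    samples: list                 # retained Sample objects
    settings: dict
    acceptance_rate: float

    def n_shifts_posterior_mean(self) -> float:
        return float(np.mean([len(s.shift_edges) for s in self.samples]))

    def branch_summary_tsv(self) -> str:
        lines = ["child_node\tshift_prob\tmedian_rate"]
        for i in range(1, self.tree.n_nodes):
            lines.append(f"{i}\t{self.shift_prob[i]:.6g}\t"
                         f"{self.median_rate[i]:.6g}")
        return "\n".join(lines) + "\n"

    def chain_tsv(self) -> str:
        lines = ["sample\tlnL\tn_classes\tpainting"]
        for k, s in enumerate(self.samples):
            lines.append(f"{k}\t{s.loglik:.8g}\t{s.n_classes}\t"
                         f"{s.painting_hash() or '-'}")
        return "\n".join(lines) + "\n"


def _edge_classes(tree, shift_edges):
    """Era-style class label per node; "0" at the root."""
    cls = np.zeros(tree.n_nodes, dtype=np.int64)
    lab = {0: 0}
    nxt = 1
    shift_set = set(shift_edges)
    for i in range(1, tree.n_nodes):
        if i in shift_set:
            cls[i] = i
        else:
            cls[i] = cls[tree.parent[i]]
    return cls


def _loglik_state(tree, x, se2, elen, shift_edges, log_rates):
    cls = _edge_classes(tree, shift_edges)
    rate = np.empty(tree.n_nodes)
    for i in range(1, tree.n_nodes):
        rate[i] = math.exp(log_rates[int(cls[i])])
    rate[0] = 0.0
    ll, _ = bm_pruning_loglik(tree, x, elen * rate, se2)
    return ll


def _adjacent_edges(tree, e):
    """Edges sharing a node with edge e (parent's edge, siblings,
    children); root itself has no edge."""
    out = []
    p = tree.parent[e]
    if p != 0 and p != -1:
        out.append(int(p))
    for s in tree.children[p]:
        if s != e:
            out.append(int(s))
    out.extend(int(c) for c in tree.children[e])
    return out


def log_prior_nshifts(k: int, lam: float) -> float:
    # un-normalized truncated Poisson
    return k * math.log(lam) - math.lgamma(k + 1)


def run_rjmcmc(tree: Phylogeny, data: TraitData, generations: int = 100_000,
               thinning: int = 100, burnin_frac: float = 0.25,
               seed: int = 0, priors: Priors = None,
               rate_step_sd: float = 0.35,
               edge_space=None) -> RateScanResult:
    """Sample rate-shift configurations; see the module docstring.

    Defaults follow the conventional chain settings: 100,000
    generations, sampling every 100, first 25% discarded as burn-in.
    ``edge_space`` optionally restricts the candidate shift edges (used
    e.g. for exact-enumeration calibration checks on tiny trees).
    """
    if generations < 1000:
        raise ValueError("generations must be >= 1000")
    priors = priors or Priors()
    rng = np.random.default_rng(int(seed))
    x, se2 = data.aligned(tree)
    elen = tree.edge_length.copy()
    if edge_space is None:
        edge_space = list(range(1, tree.n_nodes))
    edge_space = sorted(int(e) for e in edge_space)
    E = len(edge_space)
    s2_bm, _ = bm_analytic_mle(tree, x)
    mu0 = (math.log(s2_bm) if priors.log_rate_mean is None
           else priors.log_rate_mean)
    sd0 = priors.log_rate_sd
    lam = priors.shift_rate

    def lp_rate(lr):
        return -0.5 * ((lr - mu0) / sd0) ** 2   # constants cancel

    shifts = []                       # sorted list of shift edges
    log_rates = {0: math.log(s2_bm)}  # class label -> log rate
    ll = _loglik_state(tree, x, se2, elen, shifts, log_rates)

    p_add, p_rem, p_move, p_rate = 0.25, 0.25, 0.20, 0.30
    samples = []
    n_acc = 0
    n_prop = 0
    consecutive_rejects = 0
    all_edges = edge_space
    space_set = set(edge_space)

    for g in range(1, generations + 1):
        u = rng.random()
        accepted = False
        if u < p_add:
            if len(shifts) < E:
                free = [e for e in all_edges if e not in shifts]
                e_new = int(free[rng.integers(len(free))])
                lr_new = rng.normal(mu0, sd0)      # draw from prior
                new_shifts = sorted(shifts + [e_new])
                new_rates = dict(log_rates)
                new_rates[e_new] = lr_new
                ll_new = _loglik_state(tree, x, se2, elen, new_shifts,
                                       new_rates)
                k = len(shifts)
                log_a = (ll_new - ll
                         + log_prior_nshifts(k + 1, lam)
                         - log_prior_nshifts(k, lam)
                         + math.lgamma(k + 2) + math.lgamma(E - k)
                         - math.lgamma(k + 1) - math.lgamma(E - k + 1)
                         + math.log(p_rem / (k + 1))
                         - math.log(p_add / len(free)))
                # new rate proposed from its prior: density cancels, J = 1
                if math.log(rng.random()) < log_a:
                    shifts, log_rates, ll = new_shifts, new_rates, ll_new
                    accepted = True
            n_prop += 1
        elif u < p_add + p_rem:
            if shifts:
                j = int(rng.integers(len(shifts)))
                e_old = shifts[j]
                new_shifts = shifts[:j] + shifts[j + 1:]
                new_rates = dict(log_rates)
                lr_old = new_rates.pop(e_old)
                ll_new = _loglik_state(tree, x, se2, elen, new_shifts,
                                       new_rates)
                k = len(shifts)
                n_free_after = E - (k - 1)
                log_a = (ll_new - ll
                         + log_prior_nshifts(k - 1, lam)
                         - log_prior_nshifts(k, lam)
                         + math.lgamma(k) + math.lgamma(E - k + 2)
                         - math.lgamma(k + 1) - math.lgamma(E - k + 1)
                         + math.log(p_add / n_free_after)
                         - math.log(p_rem / k))
                # removed rate's prior cancels the reverse proposal density
                if math.log(rng.random()) < log_a:
                    shifts, log_rates, ll = new_shifts, new_rates, ll_new
                    accepted = True
            n_prop += 1
        elif u < p_add + p_rem + p_move:
            if shifts:
                j = int(rng.integers(len(shifts)))
                e_old = shifts[j]
                adj = [a for a in _adjacent_edges(tree, e_old)
                       if a in space_set]
                if adj:
                    e_new = int(adj[rng.integers(len(adj))])
                    if e_new not in shifts:
                        new_shifts = sorted(shifts[:j] + shifts[j + 1:]
                                            + [e_new])
                        new_rates = dict(log_rates)
                        new_rates[e_new] = new_rates.pop(e_old)
                        ll_new = _loglik_state(tree, x, se2, elen,
                                               new_shifts, new_rates)
                        adj_rev = [a for a in _adjacent_edges(tree, e_new)
                                   if a in space_set]
                        log_a = (ll_new - ll
                                 + math.log(len(adj))
                                 - math.log(len(adj_rev)))
                        if math.log(rng.random()) < log_a:
                            shifts, log_rates, ll = (new_shifts, new_rates,
                                                     ll_new)
                            accepted = True
            n_prop += 1
        else:
            labels = list(log_rates.keys())
            lab = labels[int(rng.integers(len(labels)))]
            lr_old = log_rates[lab]
            lr_new = lr_old + rng.normal(0.0, rate_step_sd)
            new_rates = dict(log_rates)
            new_rates[lab] = lr_new
            ll_new = _loglik_state(tree, x, se2, elen, shifts, new_rates)
            log_a = ll_new - ll + lp_rate(lr_new) - lp_rate(lr_old)
            if math.log(rng.random()) < log_a:
                log_rates, ll = new_rates, ll_new
                accepted = True
            n_prop += 1

        if accepted:
            n_acc += 1
            consecutive_rejects = 0
        else:
            consecutive_rejects += 1
            if consecutive_rejects >= 1000 and n_acc == 0:
                raise RuntimeError(
                    "rjMCMC: zero acceptance over 1000 consecutive "
                    f"proposals (lnL={ll:.3f}, k={len(shifts)}); check "
                    "data scaling and priors")

        if g % thinning == 0:
            samples.append(Sample(shift_edges=tuple(shifts),
                                  log_rates=dict(log_rates), loglik=ll))

    n_burn = int(round(burnin_frac * len(samples)))
    kept = samples[n_burn:]

    n = tree.n_nodes
    shift_prob = np.zeros(n)
    rate_samples = [[] for _ in range(n)]
    for s in kept:
        cls = _edge_classes(tree, s.shift_edges)
        in_shift = set(s.shift_edges)
        for i in range(1, n):
            if i in in_shift:
                shift_prob[i] += 1
            rate_samples[i].append(math.exp(s.log_rates[int(cls[i])]))
    shift_prob /= max(len(kept), 1)
    median_rate = np.zeros(n)
    for i in range(1, n):
        median_rate[i] = np.median(rate_samples[i]) / s2_bm

    return RateScanResult(
        tree=tree, shift_prob=shift_prob, median_rate=median_rate,
        samples=kept,
        settings={"generations": generations, "thinning": thinning,
                  "burnin_frac": burnin_frac, "seed": int(seed),
                  "priors": {"shift_rate": lam, "log_rate_sd": sd0,
                             "log_rate_mean": mu0},
                  "sigma2_bm": s2_bm},
        acceptance_rate=n_acc / max(n_prop, 1))


def enumerate_painting_posterior(tree: Phylogeny, data: TraitData,
                                 edge_space, priors: Priors = None,
                                 n_quad: int = 40) -> dict:
    """Exact posterior probability of every shift configuration within
    ``edge_space``, marginalized over class rates by Gauss-Hermite
    quadrature against the Normal log-rate prior.

    Feasible for small edge spaces only (2^|space| configurations,
    n_quad^classes nodes each); serves as the independent oracle for
    the rjMCMC sampler.
    """
    from itertools import combinations, product

    priors = priors or Priors()
    edge_space = sorted(int(e) for e in edge_space)
    E = len(edge_space)
    if E > 4:
        raise ValueError("enumeration limited to <= 4 candidate edges")
    x, se2 = data.aligned(tree)
    elen = tree.edge_length.copy()
    s2_bm, _ = bm_analytic_mle(tree, x)
    mu0 = (math.log(s2_bm) if priors.log_rate_mean is None
           else priors.log_rate_mean)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    lognodes = mu0 + priors.log_rate_sd * nodes
    logw = np.log(weights / weights.sum())

    out = {}
    for k in range(E + 1):
        for config in combinations(edge_space, k):
            labels = [0] + list(config)
            terms = []
            for combo in product(range(n_quad), repeat=len(labels)):
                log_rates = {lab: float(lognodes[j])
                             for lab, j in zip(labels, combo)}
                ll = _loglik_state(tree, x, se2, elen, list(config),
                                   log_rates)
                terms.append(ll + sum(logw[j] for j in combo))
            marg = float(np.logaddexp.reduce(terms))
            lp = (log_prior_nshifts(k, priors.shift_rate)
                  - (math.lgamma(E + 1) - math.lgamma(k + 1)
                     - math.lgamma(E - k + 1)))
            out[config] = marg + lp
    z = np.logaddexp.reduce(list(out.values()))
    return {cfg: math.exp(v - z) for cfg, v in out.items()}


def map_painting_ml(tree: Phylogeny, data: TraitData,
                    shift_edges) -> FitResult:
    """ML multi-rate BM fit for a fixed shift configuration.

    Rate classes come from the era-style painting; k counts one rate per
    class plus the root state.
    """
    painting = shift_branches_to_era_map(tree, shift_edges)
    labels = painting.labels
    x, se2 = data.aligned(tree)
    cls_of_edge = np.zeros(tree.n_nodes, dtype=np.int64)
    lab_index = {l: j for j, l in enumerate(labels)}
    for i in range(1, tree.n_nodes):
        cls_of_edge[i] = lab_index[painting.edge_label(i)]
    elen = tree.edge_length
    # every class must own some branch length
    tot = np.zeros(len(labels))
    for i in range(1, tree.n_nodes):
        tot[cls_of_edge[i]] += elen[i]
    empty = [labels[j] for j in range(len(labels)) if tot[j] == 0]
    if empty:
        raise ValueError(f"rate classes with zero total branch length: {empty}")

    s2_bm, _ = bm_analytic_mle(tree, x)

    def nll(lv):
        ev = elen * np.exp(lv)[cls_of_edge]
        ev[0] = 0.0
        try:
            ll, _ = bm_pruning_loglik(tree, x, ev, se2)
        except ValueError:
            return 1e100
        return -ll

    v0 = np.full(len(labels), math.log(s2_bm))
    res = minimize(nll, v0, method="L-BFGS-B",
                   bounds=[(math.log(1e-10), math.log(1e6 * s2_bm))]
                   * len(labels))
    rates = {l: float(math.exp(v)) for l, v in zip(labels, res.x)}
    ev = elen * np.exp(res.x)[cls_of_edge]
    ev[0] = 0.0
    ll, x0 = bm_pruning_loglik(tree, x, ev, se2)
    k = len(labels) + 1
    spec = ModelSpec("BMS", rates, x0=x0)
    return FitResult(spec=spec, loglik=float(ll), k=k, n=len(x),
                     aicc=aicc(ll, k, len(x)), converged=bool(res.success))


def best_sample_aic(result: RateScanResult) -> float:
    """AICc of the chain's maximum-likelihood sample, with k = number of
    rate classes in that sample + 1 (root state)."""
    if not result.samples:
        raise ValueError("empty chain")
    best = max(result.samples, key=lambda s: s.loglik)
    n = result.tree.n_tips
    return aicc(best.loglik, best.n_classes + 1, n)
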