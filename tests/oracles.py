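"""Independent oracles used by the test suite.

The joint-covariance oracle builds the full (all-nodes) Gaussian moments
edge by edge through conditional composition -- Var(child) = d^2
Var(parent) + injection, Cov(child, v) = d Cov(parent, v) -- which is an
algorithmically different route from the package's MRCA-factorized
recursion, and exact for every piecewise-constant model.
"""

import math

import numpy as np


def joint_moments_oracle(tree, painting, spec):
    """(tip mean, tip covariance) by sequential Gaussian composition."""
    s2, al, th, x0 = spec.resolve(painting)
    acdc = spec.family == "ACDC"
    r = float(spec.r)
    n = tree.n_nodes
    h = tree.height
    mean = np.zeros(n)
    cov = np.zeros((n, n))
    mean[0] = x0
    for i in range(1, n):       # preorder: parent fully known
        p = tree.parent[i]
        m = mean[p]
        row = cov[p].copy()
        v = cov[p, p]
        t0 = h[p]
        for dur, lab in painting.segments[i]:
            if dur == 0:
                continue
            if acdc:
                if abs(r) < 1e-12:
                    inj = s2[lab] * dur
                else:
                    inj = s2[lab] * (math.exp(r * (t0 + dur))
                                     - math.exp(r * t0)) / r
                d = 1.0
            else:
                a = al[lab]
                if a * dur < 1e-12:
                    d, inj = 1.0, s2[lab] * dur
                else:
                    d = math.exp(-a * dur)
                    inj = s2[lab] * (1 - d * d) / (2 * a)
                    m = th[lab] + (m - th[lab]) * d
            row = row * d
            v = v * d * d + inj
            t0 += dur
        mean[i] = m
        cov[i, :] = row
        cov[:, i] = row
        cov[i, i] = v
    tips = tree.tip_indices
    return mean[tips], cov[np.ix_(tips, tips)]


def mvn_logpdf(x, mu, V):
    n = len(x)
    sign, logdet = np.linalg.slogdet(V)
    assert sign > 0
    r = x - mu
    return float(-0.5 * (n * math.log(2 * math.pi) + logdet
                         + r @ np.linalg.solve(V, r)))


def mk2_enumeration_loglik(tree, tip_states, q01, q10, prior=(0.5, 0.5)):
    """Mk2 likelihood by summation over all internal-state assignments."""
    from itertools import product
    from scipy.linalg import expm

    Q = np.array([[-q01, q01], [q10, -q10]])
    P = {i: expm(Q * tree.edge_length[i]) for i in range(1, tree.n_nodes)}
    internals = [i for i in range(tree.n_nodes) if tree.children[i]]
    tips = {int(i): int(tip_states[tree.labels[i]])
            for i in tree.tip_indices}
    total = 0.0
    for assign in product((0, 1), repeat=len(internals)):
        state = dict(zip(internals, assign))
        state.update(tips)
        lik = prior[state[0]]
        for i in range(1, tree.n_nodes):
            lik *= P[i][state[tree.parent[i]], state[i]]
        total += lik
    return math.log(total)
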