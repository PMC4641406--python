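"""Likelihoods and ML fitting for continuous-trait evolution models.

Families
--------
``BM1``   Brownian motion, one rate sigma^2.
``BMS``   Brownian motion with one rate per regime of a painting.
``ACDC``  BM whose rate changes exponentially through time,
          sigma^2(t) = sigma0^2 * exp(r t); r < 0 is the decelerating
          "early burst" variant, r > 0 the accelerating one.
``OU1``   Single-regime Ornstein-Uhlenbeck (sigma^2, alpha, theta).
``OUM / OUMV / OUMA / OUMVA``
          Multi-regime OU where optima / optima+rates / optima+selection
          / all three vary among the regimes of a painting.

All tip means and covariances come from one root-to-tip recursion over
painting segments with piecewise-constant (sigma^2_k, alpha_k, theta_k):
along a segment of duration dt the mean relaxes toward theta_k at rate
alpha_k and the variance decays by exp(-2 alpha_k dt) while receiving an
injection sigma^2_k (1 - exp(-2 alpha_k dt)) / (2 alpha_k); BM segments
are the alpha -> 0 limit.  The covariance of two tips is the variance
accumulated at their MRCA times the exp(-alpha dt) decay products along
both descending paths.

The OU root state is pinned at the root regime's optimum (non-stationary
start); this convention is stated in the package docs and can be
overridden by passing an explicit ``x0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .phylo import Phylogeny
from .regimes import RegimeMap

__all__ = [
    "TraitData", "ModelSpec", "FitResult", "ModelComparison",
    "trait_moments", "loglik", "fit", "aicc", "compare", "blomberg_k",
    "bm_pruning_loglik", "FAMILIES",
]

FAMILIES = ("BM1", "BMS", "ACDC", "OU1", "OUM", "OUMV", "OUMA", "OUMVA")
_OU_FAMILIES = ("OU1", "OUM", "OUMV", "OUMA", "OUMVA")
_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------

@dataclass
class TraitData:
    """Tip trait values with optional per-tip standard errors."""

    values: dict                      # tip label -> float
    se: dict = None                   # tip label -> SE >= 0, or None

    def __post_init__(self):
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite trait value for {k}")
        if self.se is not None:
            for k, s in self.se.items():
                if s < 0:
                    raise ValueError(f"negative SE for {k}")

    def aligned(self, tree: Phylogeny):
        """(values, se2) arrays in the tree's tip-index order."""
        labels = tree.tip_labels
        missing = [l for l in labels if l not in self.values]
        extra = [l for l in self.values if l not in set(labels)]
        if missing or extra:
            raise KeyError(f"trait/tree label mismatch: missing={missing}, "
                           f"extra={extra}")
        x = np.array([self.values[l] for l in labels])
        if self.se is None:
            se2 = np.zeros(len(labels))
        else:
            se2 = np.array([self.se.get(l, 0.0) ** 2 for l in labels])
        return x, se2

    @classmethod
    def from_tsv(cls, text: str) -> "TraitData":
        values, se = {}, {}
        for ln in text.strip().splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if parts[0].lower() in ("label", "species", "tip"):
                continue
            values[parts[0]] = float(parts[1])
            if len(parts) > 2 and parts[2] != "":
                se[parts[0]] = float(parts[2])
        return cls(values, se or None)


def _as_map(param, labels, name):
    """Broadcast a scalar parameter over regime labels."""
    if param is None:
        return None
    if isinstance(param, dict):
        missing = [l for l in labels if l not in param]
        if missing:
            raise ValueError(f"{name} missing for regimes {missing}")
        return {l: float(param[l]) for l in labels}
    return {l: float(param) for l in labels}


@dataclass
class ModelSpec:
    """A model family plus its parameter values.

    ``sigma2``/``alpha``/``theta`` may be scalars (broadcast over all
    regimes) or dicts keyed by regime label.  ``r`` is the ACDC
    exponent.  ``x0`` is the root state; for OU families ``x0=None``
    means "pinned at the root regime's optimum".
    """

    family: str
    sigma2: object
    alpha: object = None
    theta: object = None
    r: float = 0.0
    x0: float = None
    common_se: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def resolve(self, painting: RegimeMap):
        """Per-regime parameter dicts plus the effective root state."""
        labels = painting.labels
        s2 = _as_map(self.sigma2, labels, "sigma2")
        if any(v < 0 for v in s2.values()):
            raise ValueError("sigma2 must be >= 0")
        if self.family in _OU_FAMILIES:
            al = _as_map(self.alpha, labels, "alpha")
            th = _as_map(self.theta, labels, "theta")
            if any(a < 0 for a in al.values()):
                raise ValueError("alpha must be >= 0")
            x0 = th[painting.root_label] if self.x0 is None else float(self.x0)
        else:
            al = {l: 0.0 for l in labels}
            th = {l: 0.0 for l in labels}
            if self.x0 is None:
                raise ValueError(f"{self.family} requires an explicit x0")
            x0 = float(self.x0)
        if not all(np.isfinite(v) for d in (s2, al, th)
                   for v in d.values()) or not np.isfinite(x0):
            raise ValueError("non-finite model parameters")
        return s2, al, th, x0

    def param_count(self, painting: RegimeMap, se_mode: str = "none") -> int:
        k = len(painting.labels)
        base = {"BM1": 2, "BMS": k + 1, "ACDC": 3, "OU1": 3,
                "OUM": k + 2, "OUMV": 2 * k + 1, "OUMA": 2 * k + 1,
                "OUMVA": 3 * k}[self.family]
        return base + (1 if se_mode == "common" else 0)

    def to_dict(self) -> dict:
        def plain(v):
            return v if not isinstance(v, dict) else dict(v)
        return {"family": self.family, "sigma2": plain(self.sigma2),
                "alpha": plain(self.alpha), "theta": plain(self.theta),
                "r": self.r, "x0": self.x0, "common_se": self.common_se}


# ---------------------------------------------------------------------
# Model-implied moments and likelihood
# ---------------------------------------------------------------------

def _edge_segments(tree, painting, i):
    segs = painting.segments[i]
    if tree.edge_length[i] == 0 and not segs:
        return []
    return segs


def trait_moments(tree: Phylogeny, painting: RegimeMap, spec: ModelSpec):
    """Model-implied tip mean vector and tip covariance matrix.

    Returns ``(mean, cov)`` in the tree's tip-index order.  Per-tip SEs
    are *not* added here; :func:`loglik` adds them to the diagonal.
    """
    s2, al, th, x0 = spec.resolve(painting)
    n = tree.n_nodes
    h = tree.height
    m = np.zeros(n)          # mean at node
    S = np.zeros(n)          # variance accumulated at node
    logD = np.zeros(n)       # log of cumulative decay product from root
    m[0] = x0
    acdc = spec.family == "ACDC"
    r = float(spec.r)
    for i in range(1, n):
        p = tree.parent[i]
        mi, Si, Li = m[p], S[p], logD[p]
        t0 = h[p]
        for dur, lab in painting.segments[i]:
            if dur == 0:
                continue
            if acdc:
                sig0 = s2[lab]
                if abs(r) < 1e-12:
                    inj = sig0 * dur
                else:
                    inj = sig0 * (math.exp(r * (t0 + dur)) - math.exp(r * t0)) / r
                Si += inj
            else:
                a, sg, t_opt = al[lab], s2[lab], th[lab]
                if a * dur < 1e-15:
                    Si += sg * dur
                else:
                    e1 = math.exp(-a * dur)
                    mi = t_opt + (mi - t_opt) * e1
                    # -expm1(-2 a dt) stays accurate as a -> 0
                    Si = (Si * e1 * e1
                          - sg * math.expm1(-2.0 * a * dur) / (2.0 * a))
                    Li += -a * dur
            t0 += dur
        m[i], S[i], logD[i] = mi, Si, Li

    tips = tree.tip_indices
    mrca = tree.mrca_matrix()
    Ld = logD[tips]
    cov = S[mrca] * np.exp(Ld[:, None] + Ld[None, :] - 2.0 * logD[mrca])
    np.fill_diagonal(cov, S[tips])
    return m[tips], cov


def loglik(tree: Phylogeny, painting: RegimeMap, spec: ModelSpec,
           data: TraitData) -> float:
    """Multivariate-normal log-likelihood of the tip data under the
    model-implied moments; SE^2 terms (per-tip and/or common) are added
    to the covariance diagonal."""
    x, se2 = data.aligned(tree)
    mu, V = trait_moments(tree, painting, spec)
    V = V + np.diag(se2 + spec.common_se ** 2)
    r = x - mu
    try:
        c, low = cho_factor(V, check_finite=False)
    except np.linalg.LinAlgError:
        raise ValueError("singular model covariance matrix (check for "
                         "duplicate zero-length tips or sigma2 -> 0)")
    if not np.all(np.isfinite(c.diagonal())) or np.any(c.diagonal() <= 0):
        raise ValueError("singular model covariance matrix")
    logdet = 2.0 * np.sum(np.log(c.diagonal()))
    quad = float(r @ cho_solve((c, low), r, check_finite=False))
    return -0.5 * (len(x) * _LOG2PI + logdet + quad)


# ---------------------------------------------------------------------
# Fast BM pruning (used heavily by the rjMCMC rate scan)
# ---------------------------------------------------------------------

def bm_pruning_loglik(tree: Phylogeny, x: np.ndarray, edge_var: np.ndarray,
                      se2: np.ndarray = None):
    """Profile log-likelihood of BM with per-edge variances in O(n).

    ``edge_var[i]`` is the trait variance accumulated along the edge
    above node ``i`` (edge length times that edge's rate).  The root
    state is profiled out at its ML value (the GLS mean), so the result
    equals ``max over x0`` of the full MVN log-likelihood.

    Returns ``(loglik, x0_hat)``.
    """
    n = tree.n_nodes
    tips = tree.tip_indices
    mean = np.zeros(n)
    var = np.zeros(n)
    if se2 is None:
        se2 = np.zeros(len(tips))
    pos = {int(t): k for k, t in enumerate(tips)}
    ll = 0.0
    for i in tree.postorder():
        ch = tree.children[i]
        if not ch:
            mean[i] = x[pos[i]]
            var[i] = se2[pos[i]]
            continue
        m1 = mean[ch[0]]
        v1 = var[ch[0]] + edge_var[ch[0]]
        for c in ch[1:]:
            m2, v2 = mean[c], var[c] + edge_var[c]
            s = v1 + v2
            if s <= 0:
                raise ValueError("zero-variance cherry: singular BM model")
            ll += -0.5 * (_LOG2PI + math.log(s) + (m1 - m2) ** 2 / s)
            m1 = (m1 * v2 + m2 * v1) / s
            v1 = v1 * v2 / s
        mean[i], var[i] = m1, v1
    if var[0] <= 0:
        raise ValueError("zero root variance: singular BM model")
    ll += -0.5 * (_LOG2PI + math.log(var[0]))
    return ll, float(mean[0])


def bm_unit_covariance(tree: Phylogeny) -> np.ndarray:
    """Tip covariance under BM with sigma^2 = 1 (shared path lengths)."""
    tips = tree.tip_indices
    h = tree.height
    return h[tree.mrca_matrix()].astype(float)


def bm_analytic_mle(tree: Phylogeny, x: np.ndarray):
    """Closed-form single-rate BM ML estimates (sigma2_hat, x0_hat)."""
    C = bm_unit_covariance(tree)
    c, low = cho_factor(C, check_finite=False)
    one = np.ones(len(x))
    Ci1 = cho_solve((c, low), one, check_finite=False)
    x0 = float(x @ Ci1 / (one @ Ci1))
    r = x - x0
    s2 = float(r @ cho_solve((c, low), r, check_finite=False) / len(x))
    return max(s2, 1e-12), x0


# ---------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------

@dataclass
class FitResult:
    spec: ModelSpec
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    n_restarts: int = 1
    se_mode: str = "none"

    def to_dict(self) -> dict:
        d = self.spec.to_dict()
        d.update(loglik=self.loglik, k=self.k, n=self.n, aicc=self.aicc,
                 converged=self.converged, se_mode=self.se_mode)
        return d


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n}, k={k} needs n > k + 1")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _pack(family, labels, se_mode, bounds_ctx):
    """Parameter layout: list of (name, label, transform, lo, hi)."""
    T, s2_hi, th_lo, th_hi = bounds_ctx
    lay = []
    k = len(labels)

    def s2(lab): lay.append(("sigma2", lab, "log", 1e-8, s2_hi))
    def alp(lab): lay.append(("alpha", lab, "log", 1e-8, 50.0 / T))
    def th(lab): lay.append(("theta", lab, "lin", th_lo, th_hi))

    if family == "BM1":
        s2(None)
        lay.append(("x0", None, "lin", th_lo, th_hi))
    elif family == "BMS":
        for l in labels: s2(l)
        lay.append(("x0", None, "lin", th_lo, th_hi))
    elif family == "ACDC":
        s2(None)
        lay.append(("r", None, "lin", -10.0 / T, 10.0 / T))
        lay.append(("x0", None, "lin", th_lo, th_hi))
    elif family == "OU1":
        s2(None); alp(None); th(None)
    elif family == "OUM":
        s2(None); alp(None)
        for l in labels: th(l)
    elif family == "OUMV":
        for l in labels: s2(l)
        alp(None)
        for l in labels: th(l)
    elif family == "OUMA":
        s2(None)
        for l in labels: alp(l)
        for l in labels: th(l)
    elif family == "OUMVA":
        for l in labels: s2(l)
        for l in labels: alp(l)
        for l in labels: th(l)
    else:
        raise ValueError(family)
    if se_mode == "common":
        lay.append(("common_se", None, "log", 1e-8, math.sqrt(s2_hi * T)))
    return lay


def _vector_to_spec(family, labels, layout, v):
    s2, al, th = {}, {}, {}
    r = 0.0
    x0 = None
    cse = 0.0
    for (name, lab, tf, lo, hi), val in zip(layout, v):
        val = math.exp(val) if tf == "log" else val
        if name == "sigma2":
            if lab is None:
                s2 = val
            else:
                s2[lab] = val
        elif name == "alpha":
            if lab is None:
                al = val
            else:
                al[lab] = val
        elif name == "theta":
            if lab is None:
                th = val
            else:
                th[lab] = val
        elif name == "r":
            r = val
        elif name == "x0":
            x0 = val
        elif name == "common_se":
            cse = val
    if family in _OU_FAMILIES:
        return ModelSpec(family, s2, al or None, th, r=0.0, x0=None,
                         common_se=cse)
    return ModelSpec(family, s2, None, None, r=r, x0=x0, common_se=cse)


def fit(tree: Phylogeny, painting: RegimeMap, family: str, data: TraitData,
        se_mode: str = "none", n_starts: int = 5,
        r_bounds: tuple = None) -> FitResult:
    """Maximum-likelihood fit of one model family.

    ``se_mode``: "none" (ignore SEs), "fixed" (use the per-tip SEs in
    ``data``), or "common" (one shared SE estimated as a free
    parameter, adding 1 to k).  ``r_bounds`` restricts the ACDC
    exponent, e.g. ``(-10/T, 0)`` for the decelerating early-burst
    variant.

    Optimization is bounded L-BFGS-B on log/linear-transformed
    parameters from ``n_starts`` deterministic starts (a grid over
    log-alpha seeded with the analytic BM rate estimate).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    labels = painting.labels
    x, se2_fixed = data.aligned(tree)
    n = len(x)
    use_data = replace(data, se=None) if se_mode in ("none", "common") else data
    T = tree.tree_height
    sd = float(np.std(x))
    if sd == 0:
        sd = max(abs(float(np.mean(x))), 1.0) * 0.1
    s2_hi = max(100.0 * float(np.var(x)) / T, 1e-6)
    th_lo, th_hi = float(x.min()) - 3 * sd, float(x.max()) + 3 * sd
    layout = _pack(family, labels, se_mode, (T, s2_hi, th_lo, th_hi))

    # parameter count = number of free coordinates in the layout
    k = len(layout)
    if n - k - 1 <= 0:
        raise ValueError(f"too few tips (n={n}) for family {family} (k={k})")

    s2_bm, x0_bm = bm_analytic_mle(tree, x)
    xbar = float(np.mean(x))

    if r_bounds is not None and family == "ACDC":
        layout = [(nm, lb, tf, (r_bounds[0] if nm == "r" else lo),
                   (r_bounds[1] if nm == "r" else hi))
                  for nm, lb, tf, lo, hi in layout]

    def start_vector(j):
        alpha0 = [1e-4 / T, 0.5 / T, 2.0 / T, 8.0 / T, 32.0 / T][j % 5]
        s2_mult = [1.0, 0.25, 4.0, 0.5, 2.0][j % 5]
        v = []
        for name, lab, tf, lo, hi in layout:
            if name == "sigma2":
                val = min(max(s2_bm * (s2_mult if family not in _OU_FAMILIES
                                       else max(1.0, 2 * alpha0 * T)), lo), hi)
            elif name == "alpha":
                val = min(max(alpha0, lo), hi)
            elif name == "theta":
                val = min(max(xbar, lo), hi)
            elif name == "x0":
                val = min(max(x0_bm, lo), hi)
            elif name == "r":
                val = lo + (hi - lo) * [0.5, 0.25, 0.75, 0.4, 0.6][j % 5]
            elif name == "common_se":
                val = min(max(0.1 * sd, lo), hi)
            v.append(math.log(val) if tf == "log" else val)
        return np.array(v)

    bounds = [(math.log(lo), math.log(hi)) if tf == "log" else (lo, hi)
              for _, _, tf, lo, hi in layout]

    def nll(v):
        spec = _vector_to_spec(family, labels, layout, v)
        try:
            return -loglik(tree, painting, spec, use_data)
        except (ValueError, np.linalg.LinAlgError):
            return 1e100

    best, best_v = None, None
    n_ok = 0
    for j in range(n_starts):
        res = minimize(nll, start_vector(j), method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 500})
        if np.isfinite(res.fun):
            n_ok += int(res.success)
            if best is None or res.fun < best:
                best, best_v = res.fun, res.x
    if best is None or best >= 1e99:
        raise ValueError(f"likelihood evaluation failed for {family}")
    spec = _vector_to_spec(family, labels, layout, best_v)
    lnL = -best
    return FitResult(spec=spec, loglik=float(lnL), k=k, n=n,
                     aicc=aicc(lnL, k, n), converged=n_ok > 0,
                     n_restarts=n_starts, se_mode=se_mode)


# ---------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------

@dataclass
class ModelComparison:
    """AICc table: names, AICc, Delta-AIC, Akaike weights."""

    names: list
    aiccs: np.ndarray
    deltas: np.ndarray
    weights: np.ndarray
    fits: list = field(default=None, repr=False)

    def best(self) -> str:
        return self.names[int(np.argmin(self.deltas))]

    def to_tsv(self) -> str:
        lines = ["model\tAICc\tdAIC\tweight"]
        for nm, a, d, w in zip(self.names, self.aiccs, self.deltas,
                               self.weights):
            lines.append(f"{nm}\t{a:.4f}\t{d:.4f}\t{w:.4f}")
        return "\n".join(lines) + "\n"


def compare(fits, names=None) -> ModelComparison:
    """Rank fitted models by AICc with Akaike weights.

    Near-ties (Delta-AIC < 0.01) are ordered with the smaller parameter
    count first.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    if names is None:
        names = [f.spec.family for f in fits]
    a = np.array([f.aicc for f in fits])
    ks = np.array([f.k for f in fits])
    order = sorted(range(len(fits)), key=lambda i: (round(a[i] / 0.01), ks[i]))
    a = a[order]
    names = [names[i] for i in order]
    fits = [fits[i] for i in order]
    d = a - a.min()
    w = np.exp(-0.5 * d)
    w /= w.sum()
    return ModelComparison(names=names, aiccs=a, deltas=d, weights=w,
                           fits=fits)


# ---------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------

def blomberg_k(tree: Phylogeny, data: TraitData) -> float:
    """Blomberg's K statistic of phylogenetic signal.

    K = (MSE0/MSE observed) / (MSE0/MSE expected under BM) where MSE0 is
    the mean squared deviation from the phylogenetically corrected (GLS)
    mean, MSE the GLS mean squared error under the BM covariance, and
    the BM expectation of the ratio is
    (tr(V) - n / (1' V^-1 1)) / (n - 1).
    """
    x, _ = data.aligned(tree)
    n = len(x)
    if n < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    V = bm_unit_covariance(tree)
    c, low = cho_factor(V, check_finite=False)
    one = np.ones(n)
    Vi1 = cho_solve((c, low), one, check_finite=False)
    a_hat = float(x @ Vi1 / (one @ Vi1))
    r = x - a_hat
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve((c, low), r, check_finite=False)) / (n - 1)
    expected = (float(np.trace(V)) - n / float(one @ Vi1)) / (n - 1)
    return (mse0 / mse) / expected
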