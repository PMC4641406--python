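# Methods

This note documents the models, conventions, numerical choices, and
known limitations of `phylotraits`. It states nothing the test suite
or `scripts/acceptance.py` does not itself compute.

## Trees and time

A `Phylogeny` is a rooted tree with branch lengths in relative time.
The root sits at height 0 and time increases toward the tips, so an
ultrametric tree has all tips at the tree height *T*; traitgrams read
root → present, left → right. Polytomies are allowed everywhere.
Zero-length edges are accepted with a warning (they change none of the
likelihood math but make tips exchangeable, which turns the model
covariance singular if two zero-length sister tips carry no
measurement error). Newick parsing and writing go through dendropy;
branch lengths are mandatory on every non-root edge — a missing length
raises instead of defaulting, because silently assuming 0 or 1 changes
every downstream quantity. Bracket (NHX/figtree) comments are dropped
with a warning.

`prune_tips` takes an induced subtree and collapses the resulting
degree-2 nodes with edge lengths summed, so tip heights and patristic
distances among kept tips are exactly preserved (tested against the
full tree's distance matrix).

## Regime paintings

A `RegimeMap` assigns a piecewise-constant regime label along every
edge; segment durations on an edge must sum to the edge length (tol
1e-9). Two constructors cover the common cases:

- **From discrete node states** (`states_to_regime_map`): each edge is
  painted uniformly with the state of its *child* node. This is the
  usual convention in multi-regime OU software; the alternative
  (parent-state painting) shifts every regime boundary one edge
  rootward and is not offered.
- **Era style from shift edges** (`shift_branches_to_era_map`): each
  shift edge opens a new class that applies to the shift edge itself
  and its whole descendant clade until overridden by a nested shift.

Ancestral states for painting come from the 2-state Mk model
(`fit_mk2`): ER or ARD rates bounded in [1e-8, 100/*T*], optimized by
L-BFGS-B from three log-spaced starts; the pruning likelihood uses the
closed-form 2×2 transition matrix, and marginal ancestral
probabilities come from the standard outside/re-rooting recursion
(both validated against exhaustive enumeration over all internal-state
assignments on small trees). Node states for painting are the argmax
of the marginals, with exact ties resolved toward the parent's state
to keep paintings parsimonious. Whether regimes should be painted from
marginal reconstructions, joint reconstructions, or stochastic maps is
genuinely open; marginal-argmax is the documented choice here, and
user-supplied paintings bypass it entirely. The root prior is flat by
default (stationary optional).

## Likelihoods

All families reduce to one root-to-tip recursion over painting
segments with piecewise-constant (σ²ₖ, αₖ, θₖ). Along a segment of
duration Δ in regime k:

    mean:      m ← θₖ + (m − θₖ)·e^{−αₖΔ}
    variance:  v ← v·e^{−2αₖΔ} + σ²ₖ(1 − e^{−2αₖΔ})/(2αₖ)
    decay:     log D ← log D − αₖΔ

BM segments are the αₖ → 0 limit (m unchanged, v ← v + σ²ₖΔ); ACDC
segments inject σ₀²(e^{rt₂} − e^{rt₁})/r using the segment's absolute
times. The covariance of two tips is the variance accumulated at
their MRCA times the decay products along both descending paths,
Cov(i,j) = v(MRCA)·D_i D_j / D²_MRCA, assembled with a cached all-tips
MRCA matrix. Per-tip SE² (and the squared common SE, when estimated)
is added to the covariance diagonal. The log-likelihood is the
multivariate-normal density via Cholesky; a non-positive-definite
covariance raises rather than being regularized.

Numerical notes: the variance injection uses `expm1`, which keeps the
α → 0 limit accurate to ~1e-12 (naively computing 1 − e^{−2αΔ} loses
six digits at αΔ ≈ 1e-11); decays are accumulated in log space so
αT in the hundreds underflows gracefully to zero covariance instead of
erroring.

This recursion is cross-validated (tests and the acceptance script)
against an independently coded oracle that composes the joint Gaussian
law of *all* nodes edge by edge — a different algorithm with the same
semantics — to 1e-8 over random trees, paintings, and every family.

**OU root handling.** The root state is pinned at the root regime's
optimum (a non-stationary start), matching the common
"root.station = FALSE" convention; an explicit `x0` overrides it. This
choice is documented because different packages disagree and the
difference is absorbed into θ̂ estimates near the root.

## Fitting and model comparison

`fit` maximizes the likelihood by bounded L-BFGS-B on log(σ²), log(α),
and linear θ/x₀/r coordinates, from five deterministic starts (a grid
over log α crossed with the closed-form single-rate BM estimates) —
reproducible without a seed. Bounds: σ² ∈ [1e-8, 100·var(x)/T],
α ∈ [1e-8, 50/T], θ and x₀ within the data range ± 3 SD,
r ∈ [−10/T, 10/T] (restrictable to one sign to fit the decelerating
and accelerating ACDC variants separately). Parameter counts: BM1 2,
ACDC 3, OU1 3 (θ doubles as the root state), BMS k+1, OUM k+2,
OUMV/OUMA 2k+1, OUMVA 3k for k regimes; the estimated common SE adds
one.

Measurement error comes in three modes: none, fixed per-tip SEs from
the data file, or a single common SE estimated as one extra free
parameter — the usual robustness check against rate/parameter-rich
artifacts.

`compare` reports AICc, ΔAIC, and Akaike weights; near-ties
(ΔAIC < 0.01) are ordered with the smaller parameter count first.
AICc uses n = number of tips.

Blomberg's K follows the ratio-of-ratios definition: observed
MSE₀/MSE (mean squared deviation from the GLS mean over the GLS mean
squared error under the BM covariance) divided by its BM expectation
(tr(V) − n/(1ᵀV⁻¹1))/(n − 1). Calibration: mean K over 1000 BM
simulations on a fixed 50-tip tree falls in [0.9, 1.1]; i.i.d. noise
on a nested tree gives mean K < 0.5.

## Rate-shift rjMCMC

The multi-rate BM model puts era-style rate classes at unknown shift
edges. Priors (the literature leaves them unstated; these are weakly
informative and match common practice in rjMCMC rate scanners): number
of shifts ~ Poisson(λ = log 2) truncated at the edge count, shift
locations uniform over edge subsets, log σ² per class ~ Normal(log
σ̂²_BM, 1.5²) centered on the single-rate ML estimate. Proposal mix:
add shift 0.25 / remove 0.25 / move to an adjacent edge 0.20 / class
log-rate random walk 0.30 (SD 0.35). New class rates are drawn from
their prior, so the prior density cancels in the dimension-change
acceptance ratio and the Jacobian is 1; invalid proposals count as
rejections, which preserves detailed balance. Defaults: 100,000
generations, thinning 100, 25% burn-in.

The BM likelihood inside the chain is evaluated by an O(n) Felsenstein
pruning with the root state profiled at its ML (GLS) value — pinned to
the full MVN route at 1e-9 in the tests — which is what makes 200k
generations on a 100-tip tree take well under a minute.

Correctness is checked three ways: (i) on a 4-tip tree with a
restricted 2-edge shift space, chain visit frequencies of all four
shift configurations match exact enumeration (rates marginalized by
40-node Gauss–Hermite quadrature against the prior) within 3
batch-means Monte Carlo SDs; (ii) single-rate null data yield no
branch above shift probability 0.3 and a posterior shift count within
0.5 of the prior mean; (iii) a 10× rate increase planted on a 20–40%
clade of a 100-tip tree puts > 0.5 posterior shift probability on the
stem edge. Reported per-branch rates are posterior medians relative to
σ̂²_BM. No significance cutoff is imposed on shift probabilities;
summaries report the raw values.

`map_painting_ml` is the non-censored ML cross-check: a fixed painting
(e.g. the supported shifts) fitted with one σ² per class,
k = #classes + 1. `best_sample_aic` instead takes the chain's best
sampled likelihood with that sample's class count; the two agree
within ~2 AICc units on well-mixed chains.

## Simulation

`simulate_realization` draws the *exact* Gaussian transition per
painting segment (OU, BM, or ACDC), so branch lengths need no
discretization; 10⁴ realizations on a 5-tip tree reproduce the
analytic tip means and covariances within 3 Monte Carlo SEs for BM1,
OU1, and OUMVA. Values are recorded at every node and at within-edge
painting breakpoints, giving the traitgram layer exact anchors for
every regime segment. Ensembles draw the root from Normal(mean, sd)
with explicit arguments (sd = 0 reproduces the mean): a posterior
distribution of root states can be plugged in via its fitted mean/sd,
but no root-posterior MCMC is bundled. Each realization runs on its
own RNG substream seeded by (seed, index), so partial re-runs are
bit-reproducible.

## Traitgrams and envelopes

`ou_bridge` implements the two-endpoint conditional expectation with
the second term anchored at x(tⱼ); a variant of the equation that
anchors both numerators at x(tᵢ) circulates and is provided behind
`as_printed=True`, but it violates the right-boundary condition
x(tⱼ) and is not used anywhere. The sinh ratio is computed as
e^{a−b}·expm1(−2a)/expm1(−2b), which neither overflows at large αΔ
nor loses precision at small; below αΔ = 1e-8 the bridge falls back
to exact linear interpolation. BM segments use the linear bridge. If a
realization lacks recorded breakpoint values on a multi-segment edge
(e.g. hand-constructed node-value dicts), interior anchors are filled
by exact Gaussian conditioning of the piecewise process on the two
node values.

The envelope grid is 512 uniform points on [0, T] plus all node
heights (so node values are recovered exactly). An edge contributes a
lineage value at time t when height(parent) ≤ t < height(child)
(closed-left: a node's value is counted once, on the child side), tips
contribute at their own height, and the root at t = 0. The "95% CI of
trait ranges" is the 2.5th empirical percentile of per-realization
minima to the 97.5th of per-realization maxima — percentiles of
extremes, not of pooled values, so the band tracks how wide the clade's
trait span can get, which is the quantity of interest when a rate
shift blows the range open. Empirical (inverted-CDF) percentiles make
the band invariant under duplicating the ensemble.

## Synthetic data

`yule_tree` simulates a crown pure-birth process (two lineages at the
root, splits at the birth rate, a final waiting time so terminal
branches are positive) and rescales the height to 1 by default —
matching the relative-time scale fitted trees use; `scale_height=None`
keeps raw Yule time (used to verify the ln-lineage-count growth law
against the birth rate). `make_recovery_dataset` bundles tree +
painting + exact-simulation traits with the generating parameters
recorded; the planted shift sits on the largest clade holding 20–40%
of the tips. Every generator is a pure function of (parameters, seed).

What the synthetic data do *not* emulate: phylogenetic error (a single
fixed tree is assumed true), non-Gaussian tail behavior, bounded
traits, trait-dependent diversification, and sampling noise beyond an
optional Gaussian SE. Passing recovery tests therefore shows
estimator correctness under the model, not robustness to model
violation on real data.

`pca_species_means` is the small data-prep utility: eigendecomposition
of the covariance matrix of untransformed species means; scores are
centered data projected on the eigenvectors, per-axis variance
fraction is eigenvalue/trace. Axis polarity is arbitrary, so each
loading vector's largest-magnitude entry is made positive and any
comparison to published axes should use magnitudes.

## Problem sizes used in the measurements

The acceptance measurements run at: 100 random trees of ≤ 8 tips for
the likelihood oracle; 10⁴ realizations for simulator moments; 100
replicates at 200 tips for BM rate recovery; 50 replicates at 300
tips for OUMVA recovery; 200k rjMCMC generations at 50 (null) and 100
(power) tips plus 400k on the 4-tip enumeration check; 1000
simulations for K calibration; 50 replicates at 200 tips for model
selection. These sizes give Monte Carlo error comfortably below each
check's tolerance while keeping a full run in minutes on one core.

## Known limitations

- OUMVA's per-regime selection strengths are weakly identified when
  α·(regime duration) is well below 1: the ML estimate of a shifted
  regime's α is upward-biased and order-1 noisy at α = 0.5 on a
  height-1 tree, and trades off against that regime's θ. The recovery
  measurement reports this honestly (σ² in both regimes and the root
  regime's α/θ recover essentially always; the shallow regime's α/θ
  pair often misses a factor-2 window). Fit ΔlnL diagnostics show the
  optimizer is not at fault — the fitted likelihood exceeds the
  generating parameters' likelihood in these cases.
- One tree at a time: uncertainty across a posterior tree sample is
  handled by the CLI batch loop, not by the likelihood machinery.
- Univariate traits only; no correlated-trait models, no Pagel
  transforms, no OU shift-point *search* (regimes/shift sets are given
  or sampled for BM rates only).
- Mk machinery is strictly 2-state with no hidden rate classes.
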