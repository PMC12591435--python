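# Methods

## Model

`hmfgraph` estimates a Gaussian graphical model: data rows are assumed
i.i.d. multivariate normal with zero mean and precision matrix Ω, and the
conditional-independence graph is read off the support of Ω. The prior on
Ω is a hierarchical, rescaled matrix-F distribution expressed as a Wishart
scale mixture:

    Ω | Φ ~ Wishart(ν,       ((ν − p − 1) Φ)⁻¹)
    Φ | B ~ Wishart(δ + p − 1, ((δ + p − 1) B)⁻¹)
    bᵢᵢ   ~ Gamma(ε₁, ε₂),    B = diag(b₁₁, …, b_pp)

The scaling of the target matrices makes the full-conditional modes a pair
of interpretable linear blends,

    Mode(Ω | ·) = (α Φ + (1 − α) S)⁻¹,   α = (ν − p − 1)/(ν + n − p − 1)
    Mode(Φ | ·) = (β B + (1 − β) Ω)⁻¹,   β = (δ + p − 1)/(δ + ν − 2)

with S = YᵀY/n the (divisor-n) sample covariance of the centered data.
α ∈ [0, 1) is the overall shrinkage weight — how little the sample
covariance is trusted — and β ∈ (0, 1] shrinks off-diagonal structure in
the latent target Φ toward the diagonal matrix B. The gamma prior on the
diagonal of B approximates a log-flat prior for small ε₁, ε₂ while keeping
the posterior proper even when p > n.

Not every (α, β) pair is admissible: δ > 0 requires ν > (p − 1)/β + 2,
i.e. α > c/(n + c) with c = (p − 1)(1 − β)/β. The shrinkage search
respects this bound (see below).

## Fitting

**GEM / iterative conditional modes.** Starting from B = Φ = Ω = I, each
sweep updates, in order: the diagonal of B by the mode of its gamma full
conditional, then Φ, then Ω by the blends above. Iteration stops when the
relative Frobenius change of Ω falls below `stop_criterion` (default 1e-6)
or after `max_iters` (default 1000) sweeps. The iteration is fully
deterministic; every inverse is computed by Cholesky (LAPACK
`dpotrf`/`dpotri`) and symmetrized. Because each step maximizes one full
conditional, the map is exactly the Gibbs sweep with draws replaced by
modes, so the Gibbs sampler doubles as a reference implementation: on
small problems the MAP lies inside the sampler's wide credible intervals
essentially everywhere (checked in the test suite).

**Gibbs sampler.** Cycles the same three conditionals, drawing Wisharts by
the Bartlett decomposition (chi-square diagonal, standard-normal
subdiagonal) from a seeded generator. Defaults: 5000 total sweeps with the
first half discarded, no thinning. It is a reference and
uncertainty-validation tool, not the production estimator.

## Choosing α: the condition-number constraint

The selected α is the smallest value whose MAP precision matrix has
condition number below that of a Ledoit-Wolf linear-shrinkage covariance
estimate of the same data (`sklearn.covariance.LedoitWolf`; eigenvalue
ratios are the same for a matrix and its inverse). A bisection over
α ∈ [0.001, 0.999] (clipped below at the admissibility bound above)
exploits that the condition number is empirically non-increasing in α;
every evaluation warm-starts the GEM from the previous solution, which
changes runtime only. Search resolution `alpha_tol` defaults to 0.005, and
the feasible upper end of the final bracket is returned. If the achieved
condition number is non-monotone across the bracket the search falls back
to a grid scan; if even maximal shrinkage cannot meet the bound (possible
on very well-conditioned, low-dimensional data, since the hierarchical
model never collapses fully onto the identity), the pipeline falls back to
the bracket top with a warning while the lower-level search API raises.

A dimension-based preset α = 10p/(10p + n) is exposed for
cluster/community-oriented analyses; it deliberately over-shrinks relative
to the constraint-selected value, which empirically densifies the
recovered graph and sharpens cluster visibility at some cost in edge
accuracy. On data with uniformly strong, equal partial correlations the
constraint-selected α can approach this preset; with heterogeneous edge
weights it is typically much smaller.

β is not tuned: the default 0.9 is used for all headline analyses and is
user-overridable.

## Edge selection

The MAP is dense, so edges are declared by an approximate posterior test.
Each off-diagonal entry gets a normal approximation N(ω̂ᵢⱼ, V̂ᵢⱼ) with

    V̂ᵢⱼ = (ν + n)(ŵᵢⱼ² + ŵᵢᵢ ŵⱼⱼ),   Ŵ = (nS + (ν − p − 1) Φ̂)⁻¹

— the variance of the Wishart full conditional of Ω at the MAP. The
equal-tailed interval of mass γ is ω̂ᵢⱼ ± z(γ)·√V̂ᵢⱼ with
z(γ) = Φ⁻¹((1+γ)/2); an edge is kept iff zero falls outside, equivalently
|ω̂ᵢⱼ|/√V̂ᵢⱼ > z(γ). The square root is deliberate: a normal equal-tailed
interval scales the quantile by the standard deviation, not the variance.

**Permutation calibration of γ.** Permuting the variable values
independently within each sample (rows keep their value multisets;
standardization upstream makes the scales comparable) destroys all
between-variable dependence. Refitting the model on permuted copies with
the *same* (α, β) as the real fit — the condition-number search is not
repeated under the null, keeping the null comparable and the cost linear —
yields, at every γ, a null edge count; the median over 50 permutations
estimates the number of false positives F̂P(γ). Two selectors consume the
resulting curves:

* **Target FDR**: smallest γ with F̂P(γ)/edges(γ) ≤ target (an empty graph
  counts as estimated FDR 0), i.e. the narrowest interval — most
  discoveries — compatible with the constraint.
* **Estimated-F1 maximum**: with T̂P = edges − F̂P and F̂N = K − T̂P, where K
  is the expected number of true edges (rule of thumb K = p), choose γ
  maximizing 2T̂P/(2T̂P + F̂P + F̂N); ties break toward the sparser graph.

Rather than a fixed γ grid, the real fit's per-edge z-scores serve as
candidate thresholds, so both selectors scan every achievable graph
exactly; a uniform 512-point γ grid remains available through
`estimate_fp_curve`. Permutation replicates use child seeds spawned from
one master seed and all warm-start from a single reference null fit, so
results are independent of execution order and bit-reproducible.

## Synthetic data

Two topologies at p variables:

* **Scale-free**: preferential-attachment tree (one edge per arriving
  node; exactly p − 1 edges).
* **Five clusters**: disconnected Erdős–Rényi blocks of near-equal size;
  no between-block edges. Within-block densities default to 0.305
  (fixed weights) and 0.206 (random weights), calibrated once so the mean
  clustering coefficient of the true networks at p = 100 matches the
  reference levels (≈ 0.303 and ≈ 0.195) of the generators being
  emulated.

Two weighting schemes place a positive-definite precision on the support:

* **fixed** — every edge gets raw weight v = 0.3; the diagonal is set to
  |λ_min| + 0.1 + u (u = 0.1). All partial correlations are equal in
  magnitude, emulating generators that set a common p-dependent value.
* **random** — the precision is drawn from a G-Wishart(b = 3, I)
  restricted to the graph. For forests this is sampled exactly via the
  upper-Cholesky construction under a children-before-parents perfect
  elimination ordering (free diagonal entries chi-distributed, free edge
  entries standard normal, non-edges completed to exact zeros). The
  resulting partial correlations span (−1, 1) with many weak edges, which
  is what makes these datasets informative about partial recovery. For
  the cyclic cluster graphs the Cholesky completion is numerically
  unstable, so random uniform(−1, 1) edge weights with a strictly
  diagonally dominant diagonal stand in; the cluster-structure summaries
  (clustering coefficient, component structure) do not depend on the
  weights.

In both schemes the covariance is rescaled to unit diagonal (a congruence
transform, so the precision support is preserved exactly) and data are
drawn i.i.d. normal from it. What this emulates — and does not: the
generators reproduce topology, weight heterogeneity and the
difficulty level of the reference simulators, but real omics data add
non-normal marginals, zero inflation, compositionality and batch
structure; passing recovery tests here demonstrates correctness of the
method under its own assumptions, not robustness to those violations. The
rank-based nonparanormal transform (shrunken ECDF truncated at
1/(4n^{1/4}√(π log n)), normal quantiles, unit-variance rescaling) is
provided for real-data preprocessing.

## Numerical and design choices

* Covariance divisor n (not n − 1): the likelihood enters all
  conditionals through nS. Columns are centered always and standardized
  by default (the permutation null assumes comparable scales).
* Initialization fixed at identity matrices; no randomness in the GEM.
* Symmetrization after every inversion suppresses floating-point
  asymmetry.
* Degenerate inputs: α = 0 with singular S raises (the blend is not
  invertible — more shrinkage is required when p > n); β = 1 is rejected
  by the fitting routine because Φ collapses onto B and δ is not
  identifiable; gamma-mode updates require shape > 1.
* Benchmarks and the acceptance script use 8–20 replicates per study cell
  (50 for the pure-topology summaries) — chosen as single-CPU problem
  sizes at which cell means are stable to well within the reported
  standard deviations — with 50 permutations per fit throughout.
* Clustering metrics: partitions of recovered graphs default to greedy
  modularity communities (robust to spurious bridge edges), with
  connected components as an alternative; mutual information is
  normalized by the arithmetic mean of entropies.

## Known limitations

* No sparsity-inducing prior: sparsity comes only from the interval test.
* The permutation null assumes exchangeable variable scales within a
  sample; unstandardized, heteroscedastic data violate it.
* The F1 selector depends on the prior guess K for the number of true
  edges; K = p is a heuristic, not an estimate.
* The normal interval approximation uses the conditional (not marginal)
  posterior variance; it narrows relative to the full posterior when α is
  very small.
* The Gibbs sampler stores all draws in memory and is practical only for
  p up to a few hundred.
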