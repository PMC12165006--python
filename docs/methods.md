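# Methods

`netspill` estimates causal effects of a binary treatment on a binary
outcome over an observed, undirected risk network when one person's
treatment may affect another's outcome (spillover), and assesses whether the
community structure that the analysis leans on is itself statistically
meaningful.

## Model and estimands

**Interference sets.** We assume *partial interference*: the network
partitions into disjoint communities, spillover may occur within a community
but not across communities, and (by *stratified interference*) a person's
potential outcome depends on others' treatments only through the treated
proportion in their community.  Communities are not known a priori; they are
detected by modularity maximization (below), which is exactly why the
significance analysis matters.

**Allocation strategies.** Counterfactual policies are Bernoulli
allocations: under coverage α each member of a community is independently
treated with probability α.  The policy probability of a treatment vector
`a_i` of community `i` is `π_i(a_i; α) = Π_j α^{a_ij} (1−α)^{1−a_ij}`, with a
leave-one-out version omitting member `j`.

**Effects (risk differences).** With `Ȳ(a; α)` the population average
potential outcome under own-treatment `a` and coverage α, and `Ȳ(α)` its
marginal analogue:

- direct: `DE(α) = Ȳ(1; α) − Ȳ(0; α)`
- spillover: `SE(α, α′) = Ȳ(0; α) − Ȳ(0; α′)`, α > α′
- total: `TE(α, α′) = Ȳ(1; α) − Ȳ(0; α′)` (≡ DE(α) + SE(α, α′))
- overall: `OE(α, α′) = Ȳ(α) − Ȳ(α′)`

**Weights.** Confounding is adjusted through a community-level propensity
score: the probability of the community's entire observed treatment vector,

    f(A_i|X_i) = ∫ Π_j h(x_ij, b)^{A_ij} (1−h(x_ij, b))^{1−A_ij} φ(b; 0, σ_b²) db,

where `h` is the inverse-logit of a mixed-effects logistic regression with a
community random intercept.  The IPW group means divide policy-weighted
outcome sums by `n_i · f(A_i|X_i)` (the full-vector propensity in the
denominator for both the arm-specific and marginal means), and population
means average the group means across communities unweighted.  Communities of
size one admit no spillover and are excluded from all models.

## Numerical choices

- **Quadrature.** `f` and the marginal likelihood use adaptive Gauss–Hermite
  quadrature (default 21 nodes), re-centered and re-scaled per community at
  the conditional mode of the integrand (vectorized Newton search,
  tolerance 1e−12, steps clipped to ±5).  At σ_b < 1e−10 the integral
  degenerates to the plain Bernoulli product, handled exactly.  21 vs 41
  nodes agree to 1e−6 relative on communities of size ≤ 30 with linear
  predictors within ±5.
- **Fitting.** The marginal likelihood is maximized by L-BFGS-B with σ_b
  bounded at 0 (boundary estimates are legitimate: no community-level
  heterogeneity).  A Nelder–Mead polish plus explicit gradient check
  backstops occasional abnormal line-search terminations; single-column
  perfect separation is detected up front and reported by column name.
- **Probability products** are computed in log space throughout; a
  community propensity below 1e−300 is a hard error rather than a silent 0.
- **Robust variance.** Standard errors come from an M-estimation sandwich
  with communities as independent units, stacking the propensity-model score
  equations with the mean equations so the uncertainty from estimating the
  weights propagates into the effect SEs.  The score Jacobian and total-
  likelihood Hessian are central finite differences (relative steps 1e−5 /
  1e−4); the cross-block uses `∂Ŷ_i/∂η = −Ŷ_i ∂log f_i/∂η` exactly.  When
  σ̂_b sits on the boundary it is excluded from the stacked parameters (the
  likelihood is not differentiable in σ there).  With a known propensity the
  sandwich reduces exactly to the per-community CLT form SD/√N.  The Wald
  multiplier is fixed at 1.96.

## Community detection

- **Greedy agglomerative** (fast-greedy): start from singletons, repeatedly
  apply the merge with the largest modularity increase, stop when no merge
  strictly increases Q (tolerance 1e−12).  Tie-breaking is deterministic:
  the pair with the lexicographically smallest (min label, max label) wins,
  labels assigned by sorted node order.
- **Leading eigenvector**: recursive bisection by the sign pattern of the
  leading eigenvector of the generalized modularity matrix (dense symmetric
  solver up to 256 nodes, ARPACK above; eigenvalue positivity tolerance
  1e−10; eigenvector sign fixed by making the largest-magnitude entry
  positive), accepting a split only if it strictly increases Q.  Each
  proposed bisection is refined by the Kernighan–Lin-style fine-tuning stage
  of the classical method — every vertex is moved once per pass in greedy
  order and the best prefix kept.  Without this stage, single misplaced
  vertices can never be corrected by further bisection and the detector
  visibly underperforms on strongly separated planted graphs (we verified
  that the unrefined variant reproduces igraph's output exactly, including
  its failures); with it, planted four-block structures are recovered
  essentially always and the refined partition's modularity weakly dominates
  the unrefined one.
- Both detectors run per connected component (a component's communities
  should not depend on the rest of the graph) and labels are unified
  afterwards.  Degree-0 nodes are rejected — isolates are removed at network
  load, and perturbed networks route through a wrapper that gives isolates
  singleton communities.

## Significance of community structure

A structure is credible if it survives small random perturbations.  For a
grid of γ we reassign `⌈γ|E|⌉` randomly chosen edges (delete + replace by a
uniformly drawn pair that was not an edge of the original graph, so exactly
that many edges differ; a degree-biased replacement variant is available),
re-detect, and measure the normalized variation of information

    VOI(C, C′) = [H(C|C′) + H(C′|C)] / log n  ∈ [0, 1]

(natural logs; 0 iff identical, 1 for singletons-vs-one-block).  Thirty
perturbed replicates per γ give the mean/min/max band.  The same analysis on
a degree-matched random graph (repeated double-edge swaps, 100·|E| attempts,
invalid proposals skipped) provides the no-structure reference band, and
horizontal reference levels give the VOI produced by randomly reassigning
10% or 20% of nodes to other existing communities (500 replicates).  The γ
at which the mean curve crosses a reference level is read off by linear
interpolation between grid points.

## Missing data

- **Covariates**: iterative random-forest imputation (100 trees, seeded):
  initialize missing cells with mode/mean, cycle over covariates in
  increasing-missingness order refitting a forest of each on all others,
  stop when the change criterion rises or after 10 rounds.
- **Outcomes (main path)**: single stochastic imputation from a mixed-
  effects logit of the outcome on the propensity covariates with a community
  random intercept, fitted to observed-outcome rows; predictions use each
  community's empirical-Bayes random-intercept mode (communities with no
  observed outcomes use the prior mode 0).  Because the random effect is
  community-specific, imputations may differ slightly between detection
  methods — by design.
- **Sensitivity variants**: a plain-logit imputation (no community term,
  hence identical imputations under any structure), and deterministic
  best/worst-case fills (best: treated→0, untreated→1; worst: reversed)
  bounding the effect sizes compatible with the observed data.
- Observed cells are never altered by any mode; single (not multiple)
  imputation is used, so imputation uncertainty is *not* propagated into the
  standard errors — a known understatement.

## Synthetic studies

The generator emulates the motivating study's scale: 24 planted communities
with right-skewed sizes (rounded lognormal(log 10, 0.55) clipped to [3, 40],
≈ 277 participants), within-community edge probability 0.30 over a random
spanning tree (guaranteeing internal connectivity and no isolates),
between-community probability 0.004, one binary confounder (prevalence 0.5)
and one standard-normal age-like covariate, ≈ 22% treated via a confounded
random-intercept logit (intercept −1.8, σ_b = 0.5), outcome probability
driven by own treatment (log-odds −1), coverage among *other* community
members (log-odds −1 per unit coverage), and the covariates, and ≈ 20%
missing-at-random outcomes driven by treatment and the binary covariate
only.  Intercepts were calibrated by simulation to those prevalence targets.
What it does **not** emulate: the real network's sparsity (generated graphs
carry roughly 800–950 edges, i.e. denser communities than a field-collected
contact network), degree heterogeneity, recruitment-driven topology, and
any unmeasured confounding — so passing tests demonstrate estimator
correctness under the stated model, not robustness to those features.

True effects are computed from the generating law either exactly — the
outcome law depends on others' treatments only through their count, so the
expectation over a Bernoulli(α) allocation is a binomial sum — or by
Monte-Carlo draws of treatment vectors; the two paths must agree within
Monte-Carlo error.

## Estimator validation design

Bias and confidence-interval coverage are verified on a dedicated
positivity-friendly generating law: 250 communities of 3–4 members, ≈ 40%
treated (centered between the evaluated coverages 0.2 and 0.6), moderate
confounding, σ_b = 0.4.  There the estimator is unbiased within Monte-Carlo
error and robust-Wald 95% intervals cover at ≈ 94–96%.

Under the study-emulating defaults (22% treated, communities up to size 40)
the community-level weights `π_i(A_i; α)/f(A_i|X_i)` are heavy-tailed:
estimates remain consistent, but Wald intervals undercover (≈ 88% at a few
hundred communities — even when the *true* propensity is supplied, so this
is a property of the estimand's finite-sample distribution, not of the
variance estimator, which we verified analytically and against a community
bootstrap).  This is precisely the regime that motivates the extreme-weight
trimming sensitivity analysis (default: drop communities with any weight
below 0.001 at any configured α, re-estimate on the rest).  Point estimates
at coverages far from the observed treatment rate can exceed 1 in absolute
value on unlucky draws — they are bounded by the largest weight, not by 1 —
and should be read together with the weight diagnostics.

## Pipeline determinism

Every stochastic stage takes an explicitly seeded generator.  The pipeline
derives child seeds from the master seed by fixed offsets (covariate
imputation +11, outcome imputation +101+method-index, perturbation curves
+201+method-index, null network +301+method-index, reference levels +401),
so any single stage can be reproduced in isolation and a full rerun is
byte-identical.

## Known limitations

- Single imputation understates variance relative to multiple imputation.
- Interference sets from modularity maximization have limited theoretical
  backing; the perturbation analysis quantifies, but does not repair, a
  fragile community structure.
- The normality of the community random effect is assumed, not tested.
- Heavy-tailed weights under sparse treatment (above) degrade interval
  coverage; trimming changes the estimand.
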