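# Methods

This note documents the statistical machinery implemented in `covforest`,
the choices made where the design was genuinely open, and what the synthetic
generators do and do not establish.

## Model and estimand

For responses **y**_i ∈ R^q (q ≥ 2) and covariates **x**_i ∈ R^p the
estimand is the conditional covariance matrix Σ_x = Cov[**y** | **x**],
treated as an unknown matrix-valued function of **x**.  No parametric form
is assumed; the only structural assumption is that Σ_x is (approximately)
piecewise-constant at the resolution the forest can resolve, i.e. that
observations close in covariate space have similar covariance matrices.
Responses are *not* mean-centered per group: the method targets data whose
conditional mean is constant (the generators draw y ~ N(0, Σ_x)); a strong
covariate-dependent mean would leak into the covariance estimates.

## Forest construction

Trees follow CART with randomized search: at each node `mtry` covariates
are drawn; numeric covariates propose up to `nsplit` random cut points
(midpoints of consecutive distinct in-node values, drawn uniformly without
replacement), categorical covariates up to `nsplit` random proper
level-subset partitions (canonicalized so each partition appears once).
Candidates leaving a child with fewer than `min_child = 2` rows are
discarded — both child covariances must be computable.  The winning
candidate maximizes √(n_L n_R)·d(Σ̂_L, Σ̂_R) with node covariances unbiased
(denominator n−1) and d the upper-triangular Euclidean distance; ties break
to the first candidate in drawn-covariate order with cut points ascending,
so growth is deterministic given the seed.

A node is terminal when it holds at most `nodesize` members (also when it
cannot produce an admissible candidate).  We read "nodesize" as a
stop-splitting threshold: it is the closest testable reading of a target
terminal-node size, and makes "nodesize ≥ sampsize ⇒ root-only tree" hold
exactly.

Each tree is grown on `sampsize = ⌊0.632 n⌋` rows drawn *without*
replacement.  Sub-sampling (rather than bootstrap) guarantees the in-bag
rows are distinct, which matters because node covariance estimates with
fewer than q+1 distinct rows are singular.  The master seed spawns one
independent RNG stream per tree; the stream draws the subsample first and
then drives split randomization, so the subsample-to-tree mapping is stable
across nodesize values (common random numbers for the tuner) and growth is
reproducible and order-independent.

## Out-of-bag estimation (BOP)

For a query **x***, tree b contributes O_b(**x***) — the rows out-of-bag
for tree b that fall in **x***'s terminal node; the estimate is the sample
covariance of the **set union** over trees.  Duplicates across trees are
counted once; a `multiset=True` option pools with multiplicity instead
(earlier bag-of-observations constructions did this), which reweights
frequently co-occurring neighbours.

For a *training* row i only trees where i is itself out-of-bag contribute,
and i is excluded from its own neighbour set by default (flag
`exclude_self`), keeping the estimate honest.  A row in-bag in every tree
is an error (raise `n_trees`); with the default 1000 trees the probability
is 0.368^1000.  BOPs with fewer than 2 members are degenerate: estimation
raises by default, can fall back to the unconditional covariance
(`on_degenerate="fallback"`), or yields NaN matrices that downstream
averages drop (`"nan"`, used internally by the tuner and the tests).

Unseen categorical levels in query rows are routed down *both* children of
any node splitting on that column and the contributions merged — new data
never hard-fails, at the cost of a mildly diffuse neighbour set for that
row.

## nodesize tuning

Candidates are round(sampsize·2^(−k)), k = 1, 2, …, kept while > q
(rounding half away from zero).  One forest per candidate is grown with
common subsamples; for consecutive levels the mean absolute difference
MAD(D, E) = 2/(q(q+1)) Σ_{i≤j} |D_ij − E_ij| between per-row OOB estimates
is averaged over rows with valid estimates at every level (row-complete,
not pairwise-complete, so all MAD_j share one population).  The selected
nodesize is s(argmin_j MAD_j), j = 1..M−1 — the largest candidate can never
be selected — with ties to the smallest j.  A single-candidate grid returns
that candidate with a warning.

## Significance tests

The statistic T = (1/n) Σ_i d(Σ̂_full(x_i), Σ̂_ctrl(x_i)) uses per-row OOB
estimates from a forest on all covariates versus a control reference:
the unconditional sample covariance Σ̂_root (global test), or the OOB
estimates of a forest grown on the control covariates only (partial test).
Pairs with degenerate estimates are dropped from the mean.

The null is built by refitting after permuting the rows of the **tested**
covariate block (jointly, preserving its internal dependence), with Y and
the control columns fixed.  For the global test the tested block is all of
X, so whole covariate rows are shuffled.  For the partial test only the
non-control columns move: permuting the control columns too would destroy
their genuine association with Y, put mass at the wrong place in the null
distribution, and (as we measured on the compound-symmetry null scenario)
push the type-I error toward 1.  Whole-row permutation remains available
via `permute="all"` for comparison.

Nodesize is tuned once on the original data (separately for the full and
control models) and reused in every permutation refit — tuning inside the
permutation loop would multiply the cost by the grid size.  The global test
therefore fits R+1 forests, the partial test 2R+2.  The p-value is the
strict-inequality estimate (1/R)#{T_r > T}, which can legitimately be 0;
`p_value_smoothed` carries the conventional (1+#{T_r ≥ T})/(1+R).  Per-
permutation forest seeds derive from the master seed and r, so the whole
test is reproducible.

## Variable importance (fit-the-fit)

Because Σ_x is unobserved, importances come from a second forest trained to
re-predict the first forest's estimates: each row's estimate is flattened
to its q(q+1)/2 upper-triangle entries and used as a multivariate response.
That forest splits by Mahalanobis impurity: node impurity
Σ_i (z_i − z̄)ᵀ V⁻¹ (z_i − z̄) with V the *root-node* covariance of the
flattened responses, regularized by adding ε·diag(V) (ε = 1e−6) when
ill-conditioned.  Fixing the metric at the root keeps the geometry constant
across the tree and the rule O(n) per candidate.  Importances are
out-of-bag permutation importances: per tree, each covariate's OOB values
are shuffled and the increase in per-response squared error — after
standardizing every response to unit variance, so large-variance covariance
entries cannot dominate — is averaged over responses and trees, then
normalized by the maximum.  Defaults: same tree count as the main forest,
mtry = ⌈p/3⌉, nodesize 5 (standard regression default; this forest is not
tuned).  The exact multivariate rule used by reference implementations is
not published; this construction is a declared substitute validated through
rank-separation behavior, not coefficient-level comparison.

## Synthetic generators

All four generators draw y_i ~ N(0, Σ_{x_i}) with Σ_{x_i} known, so
estimation error is measurable exactly.

* **dgp1**: x ~ U[−1,1], Σ_x = Ψ + B(1,x)ᵀ(1,x)B with Ψ = I₂ and
  B = [[1.0, 0.9], [0.5, −0.8]].  The published studies built on this
  design do not print their (Ψ, B); ours are declared substitutes, frozen
  in a versioned constants module, chosen so both the correlation
  (−0.25…0.32) and the variances (1.0…4.6) move visibly over x.
* **dgp2**: same with regressor (1, x + x²) — a quadratic effect that
  linear covariance-regression models misspecify.
* **dgp3**: seven N(0,1) covariates; a fixed depth-3 tree (X1 at the root,
  X2/X3 at depth two, X4–X7 at depth three, thresholds 0) assigns one of
  eight distinct base correlations ρ ∈ {0.05, …, 0.9}; Σ_x is AR(1),
  entries σ_j σ_k ρ^{|j−k|} with σ_j = 1 + ρ·j/q.  The exact tree and leaf
  values of the original design are unpublished; this is the declared
  substitute matching the stated structure.
* **dgp4**: compound symmetry with ρ_i = expit(β₀ + βᵀx_i), β₀ = 0,
  β = (2, 1, 0.5, 0, …): X1 strongest, X3 weakest — the geometry the
  partial-test power ordering relies on.  Same variance function.
* **add_noise_covariates** appends independent N(0,1) columns, truth
  unchanged.

What a green test on these generators establishes: the splitting rule
recovers covariance regimes that are axis-aligned functions of covariates;
the tests hold their level under exchangeable nulls; importances separate
informative from irrelevant covariates.  What it does not establish:
behavior under covariate-dependent means, non-Gaussian or heavy-tailed
responses, strongly correlated covariates, or q comparable to n — none of
which the generators emulate.

## Accuracy metrics

`mae_cor` averages |ρ̂ − ρ| over the strict upper triangle and observations;
`mae_sd` averages |σ̂ − σ|/σ over the diagonal (scale-free); `stein_loss`
is tr(E T⁻¹) − log det(E T⁻¹) − q, i.e. (twice) the Gaussian KL divergence
of N(0, est) **from** N(0, truth) — the direction is pinned as
KL(est ‖ truth) and estimates must be nonsingular (callers may regularize).
A zero estimated variance yields a zero correlation with a warning rather
than NaN.

## Numerical and engineering choices

* Split scores are computed from prefix sums of responses and their
  pairwise products, so evaluating K cut points of a covariate costs
  O(m q² + K q²); all-numeric nodes score every drawn covariate in one
  vectorized batch.  Tiny negative round-off under the square root is
  clamped at zero.
* Categorical level subsets are stored as 64-bit masks (≤ 64 levels per
  covariate; validated at construction).
* Permutation-test replicates, tuning forests and tree growth all derive
  from a single integer seed; two runs with the same seed are bit-identical.
* Missing values are rejected at input validation — no imputation is
  implied by the method.

## Scaled-down verification

The acceptance suite re-runs the study's qualitative claims (type-I error
near α, power increasing in n and in effect strength, estimator
consistency, importance rank separation, tuner competitiveness) at reduced
Monte-Carlo scale — tens of replicates, tens of permutations, 40–100 trees
— so it completes on one CPU in minutes.  Acceptance bands are 95% binomial
bands recomputed at the reduced replicate counts; they are wider than the
original study's, which is the honest price of the smaller scale.

## Real-data recipe (UCI thyroid-disease)

The package does not ship the clinical data.  To reproduce the cohort:
download the `sick`/`thyroid0387` composite table from the UCI
thyroid-disease repository, then (1) keep subjects aged 20–80; (2) exclude
pregnant subjects and those with euthyroid-sick syndrome, goitre,
hypopituitarism or tumour; (3) exclude subjects on antithyroid medication,
thyroxine or lithium, with I131 treatment or prior thyroid surgery;
(4) drop hyperthyroid diagnoses (too few) and rows with missing TSH, T3,
TT4 or FTI; responses are the four hormone measurements, covariates age,
sex and diagnosis (hypothyroid vs normal).  Then:

```sh
covforest test --x X.csv --y Y.csv --permutations 500 --seed 1 --out out/
covforest vimp --x X.csv --y Y.csv --seed 1 --out out/
covforest test --type partial --control sex,diagnosis --x X.csv --y Y.csv ...
```

## Known limitations

* The estimand must be a covariance that is roughly constant within
  covariate-space neighbourhoods; abrupt non-axis-aligned structure is
  smoothed.
* Estimates are sample covariances of moderate-size neighbour sets: they
  are positive-semidefinite but can be ill-conditioned for small BOPs, and
  Stein-loss evaluation may require regularization.
* The partial test assumes the tested block is exchangeable under H0
  given nothing (marginal permutation); strong dependence between tested
  and control covariates makes the null conservative or anti-conservative
  in the usual permutation-test way.
* Computation scales as O(n q²) per candidate split; very large q is
  expensive.
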