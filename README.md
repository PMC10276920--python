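# covforest — covariance regression with random forests

`covforest` estimates how the **covariance matrix** of a multivariate
response varies with covariates.  Classical multivariate regression models
the conditional mean E[**y** | **x**]; many scientific questions instead
concern the conditional *co-variability* Σ_x = Cov[**y** | **x**] — e.g. how
the correlations among thyroid hormones (TSH, T3, TT4, FTI) differ between
diagnostic groups and sexes, how biomarker co-variation changes with age, or
how microbial co-occurrence patterns shift with environment.  Σ_x is never
observed, which rules out ordinary supervised learning; `covforest` solves
the problem nonparametrically with a random forest built for this target.

## Method

Given responses **Y** (n × q, q ≥ 2) and covariates **X** (n × p, numeric
and/or categorical):

* **Splitting rule.** Trees are grown CART-style, choosing at each node the
  split maximizing

  √(n_L n_R) · d(Σ̂_L, Σ̂_R),

  where Σ̂_L, Σ̂_R are the children's unbiased sample covariance matrices and
  d(D, E) = √Σ_{i≤j} (D_ij − E_ij)² is the Euclidean distance over the upper
  triangle.  Splits therefore separate regions of covariate space with
  different response covariance.
* **Estimation.** Each tree is grown on a subsample (⌊0.632 n⌋ rows drawn
  without replacement).  For a query **x***, each tree contributes the
  *out-of-bag* training rows sharing **x***'s terminal node; the union over
  trees (the "bag of observations for prediction", BOP_oob) is an adaptive
  nearest-neighbour set, and Σ̂_x* is its sample covariance.
* **nodesize tuning.** The tree-depth parameter is tuned without a target:
  one forest per candidate nodesize (round(sampsize/2^k) > q), selecting
  the level whose out-of-bag estimates change least (smallest mean absolute
  difference) when moving to the next coarser level.
* **Significance tests.**  T = (1/n) Σ_i d(Σ̂_full(x_i), Σ̂_ctrl(x_i))
  compares the estimates under all covariates with those under a control
  set (the unconditional covariance Σ̂_root for the global test).  The null
  distribution is built by refitting on data with the *tested* covariate
  block row-permuted; p = (1/R) #{T_r > T}.
* **Variable importance.** Fit-the-fit: a second, multivariate-response
  forest (Mahalanobis split rule) re-predicts the flattened estimates, and
  covariate importances are its out-of-bag permutation importances.

Four simulation generators (`dgp1`–`dgp4`) with known per-row Σ_x —
rank-one quadratic forms in one covariate, a tree-structured AR(1) design
and a logit-driven compound-symmetry design — make every component testable
without external data, via the accuracy metrics `mae_cor`, `mae_sd` and
`stein_loss`.

## Worked example

```python
from covforest import CovarianceForest, dgp1, mae_cor

train = dgp1(n=300, seed=7)          # 1 covariate, 2 responses, known truth
test  = dgp1(n=300, seed=8)

res = CovarianceForest(train.Y, train.X).fit(n_trees=200, seed=7)
print(res.summary())

est = res.predict(test.X)            # (300, 2, 2) covariance estimates
print("MAE(correlations):", round(mae_cor(est, test.sigma), 4))

gt = res.global_test(n_permutations=100, seed=7)
print("global test: T=%.4f p=%.3f" % (gt.statistic, gt.p_value))
```

Output (exact numbers from this run):

```
Covariance Regression Forest Results
======================================
No. observations:      300
No. covariates:        1
No. responses:         2
Trees:                 200
mtry / nsplit:         1 / 10
sampsize:              189
nodesize:              24 (tuned)
OOB estimates:         300/300 rows
median BOP size:       65
nodesize grid:         3, 6, 12, 24, 47, 95
MAD trace:             0.3009, 0.2560, 0.1927, 0.1600, 0.2021
MAE(correlations): 0.0756
global test: T=1.2560 p=0.000
```

The tuned nodesize (24) is the grid value whose out-of-bag estimates were
most stable; the correlation MAE of 0.076 beats the unconditional benchmark
(0.144 on the same test set), and the global test rejects: the response
covariance demonstrably varies with the covariate.

The same operations are available from the shell:

```sh
covforest simulate --dgp 1 --n 300 --seed 7 --out sim/
covforest fit --x sim/X.csv --y sim/Y.csv --trees 200 --seed 7 --out fit/
covforest predict --model fit/model --x sim/X.csv --out pred/
covforest test --x sim/X.csv --y sim/Y.csv --permutations 100 --seed 7 --out test/
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline from scratch — simulate, fit with nodesize
tuning, predict on a fresh test set, score against the known truth, and run
the global permutation test — and writes the collected target values as
JSON.

## Real-data recipe (thyroid)

The UCI thyroid-disease data can be analysed end-to-end with the CLI after
an external download; see `docs/methods.md` for the cohort-construction
recipe (exclusion filters) and the expected analysis flow (global test,
variable importance, partial tests per covariate).
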