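# Methods

## Model and procedure

shadowVIMP tests, per predictor, the null hypothesis that the variable is
no more important to a random forest than an outcome-decoupled copy of
itself that retains every other property relevant to importance scores.

The null object is the *r-shadow*: the whole predictor matrix with one
uniformly drawn permutation applied to its **rows**. Row-wise permutation
(rather than permuting each column independently, as Boruta-style shadows
do) keeps the shadow block's correlation matrix identical to the
original's, which matters because permutation VIMP of an uninformative
variable is biased upward when the variable is correlated with others —
under independent column permutations that bias survives in the original
but not in its shadow, inflating false positives. An `n × 2p` extended
matrix `X ⊕ X_shadow` is refitted `niter` times with fresh permutations,
and scaled importances (z-scores) of all `2p` columns are recorded.

Importance is the classical OOB permutation VIMP: per tree, the error
increase on the tree's out-of-bag rows when one column is permuted within
the OOB set; per forest, the mean over trees divided by its standard error
`σ/√q` (sample sd over trees). Regression error is mean squared error;
classification error is the misclassification rate of per-tree majority
votes. The z-scores are not trusted as test statistics themselves (their
null spread is well above 1 and data-dependent); they serve only as the
scale-free quantity compared between originals and shadows.

Decision criteria (ties count against the variable; an `+∞` element keeps
p-values strictly positive, support `{k/(N+1)}`):

* per-variable: `p_j = (#{shadow_jt ≥ median_j} + 1)/(niter + 1)`.
* pooled: shadows standardized per column (across-iteration mean, sample
  sd); the original's median standardized by *its own shadow's* mean/sd;
  reference pool = all `p·niter` standardized shadow entries. The
  shadow-specific standardization preserves the 1:1 comparison inside the
  pooled reference: a shadow with structurally inflated importance
  (correlation, cardinality) shifts its original's standardized statistic
  down by the same amount.

Pre-selection: stages with strictly decreasing thresholds (default
`(30, 0.30), (120, 0.15), (1000, 0.05)`); variables with stage p-value
above the threshold are removed together with their shadows, shrinking the
extended matrix. The pooled criterion is always used in pre-selection
stages; the final stage uses the configured criterion (pooled by default).
Benjamini–Hochberg, Holm and Bonferroni adjustments are applied to the
final-stage p-values over the **full family of p original hypotheses**:
variables dropped during pre-selection enter the adjustment as p = 1
(tested, not rejected) and are reported "not assessed" (NaN) and never
selected. Adjusting only over the handful of screening survivors would
quietly shrink the multiplicity burden — with strong cross-stage dependence
of a variable's p-values, that scheme inflates the family-wise error far
above nominal on global-null data, whereas the full-family adjustment
holds the nominal level in the global-null simulations below.

`min_iterations(α, m)` gives the smallest iteration count whose p-value
granularity `1/(niter+1)` lies strictly below the Bonferroni per-test bar
`α/m`; it is computed in exact rational arithmetic because `α` is typically
a decimal literal without an exact float representation.

## Forest engine

Trees are exact best-split CART grown by a numba kernel on flat node
arrays. Bootstrap (with replacement, fraction 1.0) enters as integer
multiplicity weights; split criteria (variance reduction / Gini), leaf
values, and node sizes are all multiplicity-weighted, and only in-bag rows
are carried through node partitions. At every node exactly `mtry` candidate
columns are drawn without replacement (`mtry = floor(√P)` of the matrix
actually fitted — `√(2p)` for the extended matrix — matching standard RF
defaults applied per matrix). Defaults: minimum weighted node size to split
5 (regression) / 2 (classification), minimum leaf 1, unlimited depth —
the familiar RF defaults for each task. Thresholds are midpoints between
adjacent distinct values; among loss-equal splits the first one scanned in
the (randomized) candidate order wins. The grower is validated in the test
suite against a brute-force best-split oracle at every internal node and
against an independent CART implementation on tie-free data.

The VIMP kernel evaluates all columns of all trees in one pass over the
flattened forest; within-OOB permutations are Fisher–Yates draws seeded per
tree, and the kernel is tested for exact equality against a pure-Python
traversal reference. Trees with an empty OOB set contribute zero and are
excluded from the importance sd (they warn; at n ≥ 100 they essentially
never occur); a single-element OOB set admits only the identity permutation
and scores zero.

Categorical predictors: each column's categories are ranked once per forest
fit by mean outcome (regression) or positive-class rate (binary
classification), ties broken by label order, and the column is treated as
ordered numeric for splitting *and* permutation. Shadow categorical columns
are re-ranked against the outcome independently each iteration, so the
optimism this full-data ordering induces (strongest for high-cardinality
columns) appears in the null exactly as it does in the originals.
Multiclass outcomes are not supported.

## Randomness and reproducibility

All randomness descends from one master seed through counter-based
`SeedSequence` streams: per-stage, per-iteration (row permutation, forest
bootstrap/split seeds, VIMP permutation seeds) and per-replicate in the
benchmark loop. Iterations are independent given their seeds, so
`n_jobs > 1` changes wall time but never the trace; the same holds for
benchmark replicates. Fixed seed ⇒ bit-identical selections and exports.

## Numerical choices and degenerate inputs

* Sample (n−1) standard deviations throughout (z-scores, pooled
  standardization).
* `sd = 0` with zero mean importance (a never-split column) gives `z = 0`;
  `sd = 0` with nonzero mean is an error (undefined scaled importance).
* A shadow column whose importance never varies across iterations cannot
  be standardized for the pool. `pooled_pvalue` raises by default; the
  staged runner instead leaves such columns on the raw z-score scale
  (mean 0, sd 1) and warns. This situation requires a column that no tree
  ever split on in any iteration — impossible at full scale (10 000 trees),
  rare and benign at the reduced scale used for testing wide matrices.
* FDP is defined as 0 when nothing is selected; sensitivity is reported as
  absent (not 0) for all-null designs.
* Constant predictor columns are legal: they are never split on, score
  importance exactly 0, and end with p ≈ 1.

## Synthetic designs

Four generators with ground-truth labels drive all tests; `n = 100` per
replicate unless stated.

* **Friedman**: `y = 10 sin(πx₁x₂) + 20(x₃−0.5)² + 10x₄ + 5x₅ + ε`,
  ten i.i.d. U(0,1) columns, truth = first five.
* **Degenhardt** (high-dimensional): six latent U(0,1) variables, each
  expanded into a block of g ∈ {10, 50} correlated columns
  `x_{w,j} = υ_w + (0.01 + 0.5(j−1)/(g−1))·ν` with ν drawn per entry
  (per-column draws would make blocks rank-deficient); outcome
  `0.25 e^{4υ₁} + 4/(1+e^{−20(υ₂−0.5)}) + 3υ₃ + ε`; U(0,1) noise columns
  pad to p = 5000. Truth = blocks 1–3 (30 or 150 columns).
* **Strobl** (cardinality bias): one N(0,1) column and uniform multinomials
  with 2/4/10/20 levels; binary y with P(y=1) = 0.3/0.7 conditional on the
  binary x₂; truth = {x₂}.
* **Nicodemus null** (correlation bias): 12 standard normals, the first
  four equicorrelated at 0.9 (Cholesky factorization); a linear outcome is
  generated and then permuted, so truth is empty.

Noise terms written `N(0, c)` are read with `c` as the **variance**
(sd = √c); the module constant `NOISE_PARAM_IS_VARIANCE` flips the reading.
The choice moves no truth labels or column counts, and the signal-to-noise
ratio of every design is high enough that the operating characteristics
below are insensitive to it.

What the generators do *not* emulate: missingness, batch structure,
heavy-tailed or heteroscedastic noise, and outcome-dependent sampling.
Passing benchmarks on these designs shows calibration and power under
clean, correctly specified simulations — not robustness to real-data
pathologies.

## Benchmark protocol and reduced scale

Each experiment simulates replicates, runs the full staged selection per
replicate, scores TP/FP against the generating truth (sensitivity, type-1
error, false-discovery proportion, FWER event = any false positive), and
averages over replicates; uncertainty is a percentile bootstrap over
replicates. The package's built-in experiments run at a reduced study
scale, chosen once as the package's testing protocol and shared by the test
suite and `scripts/acceptance.py` (`shadowvimp.benchmark.DESK_SCALE`):
**30 replicates, 500 trees, stages (10, 0.30), (40, 0.15), (200, 0.05)**;
the high-dimensional check uses a single g=50 replicate with 300 trees and
stages 10/40/100. Full-scale analyses (10 000 trees, 30/120/1000
iterations, 100 replicates) are what the defaults of `StagePlan` and
`PermutationImportanceForest` encode; at 30 replicates the Monte-Carlo
standard error of a ~96% sensitivity estimate is ≈1.6 points, which should
be kept in mind when comparing single runs against tight reference bands.

Tree count interacts with staged calibration: a variable's data-fixed
chance association contributes to its z-score proportionally to √(trees),
so at reduced tree counts the cross-stage dependence of a null variable's
p-values weakens and the staged procedure becomes *more* conservative
(lower unadjusted type-1 error) than the same procedure at full scale.
The global-null experiments in the test suite measure this directly; the
error is in the safe direction.

## Known limitations

* Binary classification only; no multiclass, survival, or probability-based
  error.
* The adjustment-after-screening semantics above; no selective-inference
  correction for the pre-selection stages beyond the empirical null checks.
* Permutation p-values are conservative by construction in high dimensions
  (forest stochasticity inflates the shadow spread relative to the
  median-aggregated originals), trading some power for type-1 safety.
* No handling of missing values; impute upstream.
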