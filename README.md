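# shadowvimp

Multiple-testing-controlled variable selection for random forests.

Random-forest permutation importance (VIMP) ranks predictors but gives no
threshold for calling a variable *informative*: its null distribution is
intractable, varies with predictor correlation and categorical cardinality,
and any "top-N" cutoff selects something even from pure noise. This package
implements **shadowVIMP**: it appends an *r-shadow* block to the predictor
matrix — a copy of all of `X` with its **rows** permuted, which decouples
every column from the outcome while preserving the inter-predictor
correlation matrix exactly — refits the forest over many iterations, and
turns the comparison of each variable's importance against shadow
importances into a permutation p-value that supports standard FDR
(Benjamini–Hochberg) and FWER (Holm) adjustment.

It is aimed at biostatistical feature screening (biomarker discovery,
high-dimensional epidemiological tables) where `p >> n` and error-rate
control matters more than a ranking.

## Method

For tree `l` with out-of-bag set `B_l`, the per-tree importance of column
`x_j` is the OOB error increase when `x_j` is permuted within `B_l`
(squared error for regression, misclassification rate for binary
classification). With `q` trees, the scaled importance (z-score) is

```
VI_j = (1/q) Σ_l VI_l(x_j),        z_j = VI_j / (σ_j / √q)
```

where `σ_j` is the sample sd of the per-tree values. In each of `niter`
iterations a fresh row permutation builds the `n × 2p` extended matrix
`X ⊕ X_shadow`, a forest is fitted, and the z-scores of all `2p` columns are
recorded. Two decision criteria:

* **per-variable**: `p_j = (#{shadow_jt ≥ median(VI⃗_j)} + 1) / (niter + 1)`
  — each variable against its own shadow's distribution, with an appended
  `+∞` element so p-values are never zero.
* **pooled** (default): each shadow column is standardized by its own
  across-iteration mean/sd, each original column by *its shadow's* mean/sd
  (so a shadow that scores high for structural reasons — correlation,
  cardinality — raises the bar for its original), and the standardized
  median is referred to the pool of all `p·niter` standardized shadow
  values. The attainable p-value resolution improves from `1/(niter+1)` to
  `1/(p·niter+1)`, which is what makes Holm/BH adjustment feasible at
  realistic iteration counts.

**Pre-selection** runs the procedure in stages with decreasing thresholds
(default 30 iterations at α=0.30, then 120 at 0.15, then 1000 at 0.05),
dropping variables and their shadows between stages. Categorical predictors
are target-ordered once per forest fit and treated as ordered numeric, and
each shadow categorical is re-ordered against the outcome itself, so the
ordering-induced optimism enters the null as well.

## Worked example

```python
import shadowvimp as sv

data = sv.gen_friedman(100, seed=1)        # y = 10 sin(pi x1 x2) + 20(x3-.5)^2 + 10 x4 + 5 x5 + eps
res = sv.run_shadowvimp(
    data.X, data.y,
    [(10, 0.30), (40, 0.15), (200, 0.05)], # staged pre-selection
    n_trees=500, seed=42,
)
print(res.to_frame().to_string(index=False))
```

```
variable  median_vimp    p_raw     p_BH   p_Holm  p_Bonferroni  selected_unadj  selected_FDR  selected_FWER  last_stage
      x1    20.453697 0.000833 0.002082 0.008326      0.008326            True          True           True           3
      x2    16.079624 0.000833 0.002082 0.008326      0.008326            True          True           True           3
      x3     2.942619 0.042465 0.084929 0.254788      0.424646            True         False          False           3
      x4    26.161884 0.000833 0.002082 0.008326      0.008326            True          True           True           3
      x5    11.760127 0.000833 0.002082 0.008326      0.008326            True          True           True           3
      x6          NaN      NaN      NaN      NaN           NaN           False         False          False           1
      x7     2.071994 0.107410 0.179017 0.537052      1.000000           False         False          False           3
      x8          NaN      NaN      NaN      NaN           NaN           False         False          False           2
      x9          NaN      NaN      NaN      NaN           NaN           False         False          False           1
     x10          NaN      NaN      NaN      NaN           NaN           False         False          False           1
```

The four strong Friedman terms reach the minimum attainable pooled p-value
(`1/(6·200+1) ≈ 0.00083`) and survive every adjustment; the weak quadratic
term `x3` passes unadjusted (p = 0.042) but not the FDR/FWER thresholds in
this replicate; most noise columns are dropped during pre-selection
(`last_stage < 3`, p-values reported as NaN = not assessed at the final
stage). Adjusted p-values are computed over all 10 hypotheses — dropped
variables count as p = 1, so screening never shrinks the multiplicity
burden.

The same pipeline is exposed as a scikit-learn selector
(`sv.ShadowVimpSelector(...).fit(X, y).transform(X)`) and as a CLI:

```bash
shadowvimp simulate --design friedman --n 100 --seed 1 --out sim/
shadowvimp select --input sim/friedman.csv --outcome outcome \
    --stages "30:0.30,120:0.15,1000:0.05" --trees 10000 --seed 7 --out run/
shadowvimp benchmark --design strobl --replicates 30 --seed 3 --out bench/
```

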