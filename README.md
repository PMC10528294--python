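# dcforest

Filter-based feature selection for random-forest regression using the
**distance correlation** (dCor). The package is aimed at regression problems
with many irrelevant features — high-dimensional tabular data such as
gene-expression studies (n ≪ p) — where a forest wastes most of its splits
on noise columns unless the feature space is reduced first, and where the
relevant dependencies need not be linear.

## The method

For features X₁, …, X_p and response Y, the sample distance correlation of
a feature with the response is built from double-centered pairwise-distance
matrices. With a_jk = |x_j − x_k|, b_jk = |y_j − y_k| and

    A_jk = a_jk − ā_j· − ā_·k + ā_··   (B likewise),

the squared sample distance covariance is the V-statistic
dCov²ₙ = n⁻² Σ_jk A_jk B_jk, and

    dCorₙ(X, Y) = sqrt(dCov²ₙ(X,Y)) / (dCov²ₙ(X,X) · dCov²ₙ(Y,Y))^{1/4}.

dCor lies in [0, 1] and its population version is zero **iff** X and Y are
independent, so — unlike the Pearson correlation — it detects symmetric and
otherwise nonlinear dependencies.

The screening workflow, given a threshold grid R* ∈ {0.0, 0.1, …, 0.6}:

1. compute dCor(Y, X_j) for every feature on the training split;
2. for each R*, keep the features with dCor ≥ R* (inclusive);
3. grow a Breiman regression forest on the survivors (500 trees,
   mtry = ⌊p*/3⌋ recomputed from the reduced dimension p*, minimum node
   size 5);
4. pick the threshold whose forest attains the smallest test-set MSE.

An absolute-Pearson variant of step 1 (the "CC" filter) is included as the
linear baseline, and out-of-bag permutation variable importance
VI_j = E[(f̂(…, X̃_j, …) − f̂(…, X_j, …))²] / E[(Y − f̂(…, X̃_j, …))²]
is available for the fitted forests.

A seeded synthetic-data module reproduces the standard benchmark designs
(Gaussian AR(1) designs with Σᵢⱼ = ρ^|i−j|, the same plus 0.2 on all
off-diagonals, and the uniform cube) with linear, additive-nonlinear and
hinge-interaction responses, and a Monte-Carlo harness averages
threshold-sweep MSEs over replications into benchmark-style tables.

## Worked example

`examples/04_threshold_sweep.py` sweeps both filters on one draw of the
hinge benchmark y = 100·(X₁−0.5)²·(X₂−0.25)₊ + ε with 100 uniform features:

```
DC filter:
  threshold 0.0: 100 features, MSE  6.269
  threshold 0.1:  60 features, MSE  6.314
  threshold 0.2:   3 features, MSE  4.986
  threshold 0.3:   2 features, MSE  2.976
  threshold 0.4:   1 features, MSE  9.889
  threshold 0.5:   1 features, MSE  9.889
  threshold 0.6:   0 features, MSE    NA
  -> best threshold 0.3 (MSE 2.976)

CC filter:
  threshold 0.0: 100 features, MSE  6.269
  threshold 0.1:  16 features, MSE 10.579
  ...
  -> best threshold 0.0 (MSE 6.269)
```

At R* = 0.3 the DC filter keeps exactly the two signal features and halves
the unfiltered forest's error (2.98 vs 6.27). The Pearson filter never
improves on no filtering here: it cannot see the symmetric quadratic in X₁
(|r| ≈ 0), so any threshold that removes noise also removes X₁. `NA` marks
thresholds that removed every feature, where no forest can be grown.

The other scripts in `examples/` demonstrate the dCor statistic itself,
single-threshold screening, filtered-vs-unfiltered forests, and permutation
importance; each prints a short interpretation with its numbers.

## Command line

A thin CLI wraps the library for shell use:

```bash
dcforest simulate --model 3 --setting 4 --p 100 --seed 0 --out-prefix sim
dcforest screen   --input sim_train.csv --response y --method dc --threshold 0.3
dcforest fit      --train sim_train.csv --test sim_test.csv --response y \
                  --method dc --threshold 0.3 --importance
dcforest reproduce-table --config cfg.yaml --out-prefix table
```

Exit codes: 0 success, 2 invalid input/configuration, 3 no viable model
(the threshold removed every feature). Every run writes a JSON manifest
(seed, config, library versions) sufficient to re-run bit-identically.

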