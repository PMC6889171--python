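# Methods

## The model

For a quantitative trait measured on `n` individuals genotyped at `p`
biallelic markers (p >> n), the package starts from the standard GWAS mixed
model

    y = W a + Z g + u + e,   u ~ N(0, sg2 K),   e ~ N(0, s2 I),

where `W` holds the fixed effects (intercept and, optionally,
population-structure covariates), `Z` the marker codes, `u` the polygenic
effect with relatedness matrix `K`, and `e` the residual. The pipeline is a
two-stage screen for trait-associated SNPs:

1. **Whitening.** The variance ratio `lambda = sg2/s2` is estimated once by
   REML on the null (no-QTN) model, and the model is premultiplied by
   `C = (lambda*K + I)^(-1/2)`, after which the combined polygenic + residual
   covariance is `s2 I`. Transformed marker columns are centered and scaled
   to unit sum of squares (`sum_i x_ij = 0`, `sum_i x_ij^2 = 1`), giving the
   whitened regression `Y = X b + e`.
2. **LARS screen.** Forward least angle regression on `(X, Y)` admits
   variables in order of absolute correlation with the running residual,
   moving along equiangular directions. A LARS fit saturates after at most
   `n - 1` steps, so the screen returns `k <= n - 1` candidate SNPs. A
   Mallows-type risk trace `Cp(s) = RSS_s / sigma2_bar - n + 2s` is recorded
   per step; because the screen is run to saturation by default, the trace is
   diagnostic rather than a stopping rule.
3. **Forest ranking.** A regression random forest (bagging, per-node random
   subspaces of size `mtry`, minimum node size 5) is grown on the selected
   columns, and each candidate is scored by out-of-bag permutation importance
   (%IncMSE): for each tree, the increase in OOB mean squared error after
   permuting the variable, averaged over trees and divided by its standard
   error. Ranking the scores yields the prioritized SNP list.

Two comparators quantify what the first two stages buy: a single-stage
forest over all filtered SNPs (`run_rf_baseline`) and a group-wise
backward-elimination forest (`run_tsrf_comparator`; a best-effort
reconstruction from a textual description — it repeatedly drops the
`group_size` lowest-scoring SNPs until at most `group_size` survive).

## Parameters that matter

| parameter | default | role |
| --- | --- | --- |
| `maf_threshold` | 0.10 | drop markers with minor-allele frequency < 10% before anything else |
| `lars_max_steps` | `n - 1` | saturation bound of the screen; also the number of scored SNPs |
| `ntree` | 500 | trees per forest (the classical default) |
| `mtry` grid | {k/3, sqrt(k), k/2, k} | candidate subspace sizes, chosen by OOB MSE (ties: smallest) |
| `min_samples_leaf` | 5 | regression-forest node-size default |
| `lambda` search | 100-point log grid on [1e-5, 1e5], then bounded refinement | REML profile optimization, tolerance 1e-6 on log-lambda |
| `scaled_importance` | True | %IncMSE as mean/SE over trees; raw mean increase via flag |

Kinship is the VanRaden-style standardized cross-product `K = M M^T / p`
(column-centered, unit-variance markers; monomorphic columns excluded) — the
dominant convention in mixed-model GWAS; the source model treats `K` as
given and never specifies its construction. A precomputed kinship can be
supplied instead.

## The simulation design

`tslrf.simulate` emulates the validation study this package ships with:
n = 199 inbred individuals, p = 10,000 SNPs in {0, 1} coding at allele
frequency 0.30, laid out on five chromosome segments, with six QTNs at fixed
positions on chromosomes 1 and 2 carrying narrow-sense heritabilities
0.10 / 0.05 / 0.05 / 0.15 / 0.05 / 0.05, grand mean 10.0 and residual
variance 10.0. Effect sizes solve `b_j^2 Var(x_j) = h_j^2 sigma_P^2`
against the realized sample variance of each QTN column, with
`sigma_P^2 = 10 / (1 - 0.45) ~= 18.18`; effects are positive by default
(importance scores are sign-invariant). An optional polygenic background
term is off by default: the emulated design lists only QTNs plus residual
noise.

What the generator does **not** emulate is linkage disequilibrium: marker
columns are i.i.d. Bernoulli draws, whereas the study that motivated this
design drew its SNPs from a real *Arabidopsis* panel. Three consequences
matter for interpreting test results:

* `K` computed from i.i.d. markers is close to the identity, so the REML
  profile in `lambda` is nearly flat and the estimate often lands on a search
  bound. This is the expected behavior of a boundary-constrained variance
  ratio under a weakly informative `K`, not an optimizer failure; the
  whitening it induces is then close to a scalar rescaling. Identifiable
  null-recovery behavior is exercised in the tests with a family-structured
  `K` instead.
* without LD there is exactly one informative marker per QTN, while a real
  panel offers many tagging markers; out-of-fold prediction accuracy is
  therefore systematically worse here than on LD-rich data.
* passing score-reproduction tests shows the ranking machinery concentrates
  importance on true QTNs at the study's signal strengths; it does not show
  how the pipeline behaves under LD confounding or real population structure.
  The concentration cuts both ways: the strongest QTN's importance score runs
  *higher* here than on an LD panel, because its entire signal loads on one
  column instead of being shared among tagging neighbors.

## Numerical and design choices

* **sigma2_bar for Cp.** The classical formula wants the residual variance of
  the full OLS fit, which does not exist for p >> n; the default is the
  sample variance of `Y` (null-model estimate), configurable. The
  saturation-time trace reported by the original description of this
  procedure is arithmetically inconsistent with the formula by one unit
  (a minimum of 196 where `RSS/sigma2_bar - n + 2(n-1) >= n - 2 = 197`);
  the formula is implemented literally.
* **Intercept handling.** The screen operates on centered `Y` and centered,
  unit-sum-of-squares `X` (the intercept is projected out rather than entered
  as a competing column).
* **Ties.** LARS entry ties go to the lowest column index; importance-rank
  ties go to the original marker order; `mtry` ties go to the smallest value.
  All randomness derives from one master seed through `SeedSequence` spawns,
  so every run is bit-reproducible.
* **Collinear columns** are excluded from the LARS active set with a warning
  (singular active Gram); columns constant after whitening are dropped with a
  warning (their unit-norm scaling is undefined).
* **Prediction for unseen samples.** New samples cannot participate in the
  training-fold whitening rotation. Selected marker columns of new samples
  are standardized with the raw training centers/norms (equal to the whitened
  standardization when `C` is a scalar multiple of `I`), and forest outputs
  are mapped back to the phenotype scale via
  `yhat = ybar + (Yhat - mean(Y_train)) / c_bar`, `c_bar = tr(C)/n`. Both
  maps are exact when `lambda_hat ~ 0` and first-order otherwise.
* **Cross-validation** re-runs the entire pipeline (kinship, REML, whitening,
  LARS, forest) on each training fold; held-out samples never influence
  selection. Kinship could be shared across folds (it is phenotype-free) but
  is recomputed per fold for simplicity.
* **MAPE** is reported on the literal fraction scale (no x100) and errors on
  any zero phenotype value.
* **Pearson r** follows the standardized-score sum with `n - 1` denominators,
  normalized by `n - 1` so that `|r| <= 1`.

## Problem sizes in the shipped studies

The acceptance script runs 30 replicates of the full importance study and 3
replicates of the ten-fold CV study; the test suite uses 8 and 2. These are
the package's desk-scale choices; per-replicate importance summaries have
replicate SDs of roughly 2.4-3.5 score units, so 8-30 replicates pin the
means to within about one SD.

## Known limitations

* An out-of-fold predictor that never sees the test-fold residuals cannot
  beat the residual noise floor: under the default design
  `E|y - yhat| >= E|e| = sqrt(2 * 10 / pi) ~= 2.52` for any leakage-free
  prediction. CV MAE values below that floor are only reachable when marker
  selection sees the full data; this package deliberately refuses to do that.
* The group-wise elimination comparator follows a prose description of the
  original procedure (consecutive elimination of the lowest-scoring block)
  and is approximate; it is excluded from strict reproduction checks.
* The whitening uses the full-rank `(lambda K + I)^(-1/2)`; low-rank
  variants of the transformation used by some multi-locus methods are not
  reproducible from the available description and are out of scope.
* Heterozygote-capable ({0,1,2}) data are accepted and processed, but all
  shipped studies use inbred {0,1} coding.
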