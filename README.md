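# tslrf

Two-stage SNP prioritization for genome-wide association studies of
quantitative traits, built for the "big p, small n" regime (hundreds of
samples, 10^4-10^5 markers).

Single-marker mixed-model scans control population structure well but test
one SNP at a time; off-the-shelf machine-learning rankings (random-forest
importance on raw genotypes) ignore polygenic background and spread
importance thinly across thousands of markers. This package combines the
two ideas:

1. **Whiten** the phenotype against polygenic background and structure:
   estimate the variance ratio `lambda = sg2/s2` of the mixed model
   `y = Wa + u + e`, `u ~ N(0, sg2 K)`, by REML, and premultiply the model by
   `C = (lambda K + I)^(-1/2)` so the residual covariance becomes `s2 I`.
2. **Screen** the whitened, standardized markers with least angle
   regression (LARS), which admits at most `n - 1` candidates — the markers
   most correlated with the corrected phenotype.
3. **Rank** the candidates with a regression random forest via out-of-bag
   permutation importance (%IncMSE): the increase in OOB mean squared error
   after permuting a marker, averaged over trees and scaled by its standard
   error.

The package ships the full validation study as code: a seeded simulator for
the reference design (199 inbred individuals, 10,000 SNPs at allele
frequency 0.30, six QTNs with heritabilities 0.10/0.05/0.05/0.15/0.05/0.05,
grand mean 10, residual variance 10), plain-forest and group-elimination
comparators, and ten-fold cross-validated accuracy metrics (MAE, MAPE,
Pearson r). See `docs/methods.md` for the model, conventions and
limitations.

## Worked example

```python
from tslrf import PipelineConfig, run_tslrf
from tslrf.simulate import SimulationConfig, simulate_dataset

truth = simulate_dataset(SimulationConfig(), seed=11)   # 199 x 10,000, 6 QTNs
res = run_tslrf(truth.genotypes, truth.phenotype, PipelineConfig(seed=11))
print(res.variance_components)
print(res.top(5))
```

```
VarianceComponents(sigma_g2=0.00021365359235630011, sigma2=21.36535923563001, lam=1e-05, reml_loglik=-584.066137002931)
  marker_id chromosome  position      score  rank
0    M02130          2   5134047  26.130316     1
1    M07330          4   2838523  13.914544     2
2    M00178          1  11298200   8.258846     3
3    M06986          4   2681736   6.161990     4
4    M05850          3   3100405   5.446485     5
```

The REML ratio `lam` sits at the lower search bound: the simulated design
has no polygenic background term and the marker-derived kinship is close to
the identity, so the whitening is (correctly) near-trivial here. The
top-ranked marker `M02130` is the simulated QTN with heritability 0.15
(chromosome 2, position 5,134,228 mapped to the nearest simulated marker)
and rank 3 (`M00178`) is the heritability-0.10 QTN on chromosome 1; ranks 2
and 4-5 are false positives of this particular replicate. Scores are
%IncMSE values: `M02130`'s 26.1 means permuting it raises the forest's
out-of-bag MSE by about 26 standard errors — far above the bulk of
unrelated SNPs, whose scores hover near 0.

The command-line interface exposes the same stages:

```sh
tslrf simulate --n 199 --p 10000 --seed 1 --out data/
tslrf run --genotypes data/genotypes.tsv --phenotypes data/phenotype.tsv --out results/
tslrf evaluate --genotypes data/genotypes.tsv --phenotypes data/phenotype.tsv --method tslrf --out cv/
tslrf replicate --reps 30 --methods tslrf,rf --out study/
```

Every run writes a `manifest.json` (command line, config echo, input
digests, master seed) sufficient to reproduce its outputs bit-identically.

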