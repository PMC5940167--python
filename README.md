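# bsnreg — Bayesian whole-genome regression with skew-normal residuals

Genomic selection predicts the genetic merit of breeding candidates from
dense marker genotypes and phenotypes. The standard Bayesian whole-genome
regressions assume Gaussian residuals, but many phenotypes — disease
severity scores, flowering time, traits shaped by selection — are visibly
skewed, and a normalizing transformation is often hard to find and harder
to interpret. `bsnreg` fits the regression

y = β₀·1 + Xβ + e,  eᵢ ~ SN_C(0, σₑ², γ₁)

where X is the n×p marker matrix (0/1 DArT or 0/1/2 SNP codes, typically
p ≫ n), β carries a ridge-type prior β ~ N_p(0, σ_β² I), and the residuals
follow the **centered skew-normal** law with mean 0, variance σₑ² and
skewness γ₁ ∈ (−0.99527, 0.99527), indexed by a shape parameter
ρ ∈ (−1, 1) through γ₁ = √(2/π) ρ³ (4/π − 1)(1 − 2ρ²/π)^(−3/2). At ρ = 0
the model collapses exactly to Bayesian Ridge Regression (BRR), which the
package also implements as the comparison baseline.

Fitting uses the hidden-truncation stochastic representation: a
skew-normal variate is one coordinate of a bivariate normal conditioned on
the other being positive. Augmenting each observation with the latent
positive coordinate zᵢ makes every location parameter conditionally
Gaussian and each zᵢ truncated normal, so the model is sampled by Gibbs
updates plus adaptive random-walk Metropolis steps for (ρ, σₑ²) (tuned to
an acceptance rate of about 0.23). Model comparison uses the deviance
information criterion (DIC) with the effective number of parameters pD,
both computed from the marginal (observed-data) likelihood, and predictive
ability is assessed by replicated Monte-Carlo simulation and random 80/20
cross-validation. See `docs/methods.md` for the model account and
`docs/derivations.md` for the full conditionals.

## Worked example

Simulate a skewed trait on a synthetic binary marker panel and fit both
models:

```python
from bsnreg import (SkewNormalRegression, BayesianRidge, SimulationSettings,
                    simulate_phenotypes, synth_markers, sample_skewness)

X = synth_markers(300, 500, maf=0.5, seed=42)              # 0/1 markers
settings = SimulationSettings(n=300, p=500, rho_true=0.95,  # gamma1 ~ 0.67
                              n_replicates=1, seed=42)
y, beta_true = simulate_phenotypes(X, settings, replicate_seed=43)
print("sample skewness:", round(sample_skewness(y), 3))

bsn = SkewNormalRegression(y, X).fit(n_iter=10_000, burn_in=5_000, seed=1)
print(bsn.summary())
brr = BayesianRidge(y, X).fit(n_iter=10_000, burn_in=5_000, seed=2)
print("BRR DIC:", round(brr.dic().dic, 3))
```

Output:

```
sample skewness: 0.945
SkewNormalRegression fit: n=300, p=500, retained draws=5000
          post.mean    post.sd
beta0         3.223     0.4886
sigma2_e       2.09    0.20219
sigma2_b  0.0029251 0.00078594
rho         0.98638  0.0098586
theta = sigma2_e/sigma2_b = 714.5
pD = 48.934   DIC = 1067.508
Metropolis acceptance (rho, sigma2_e) = (0.214, 0.222)
BRR DIC: 1129.977
```

The intercept (generative value 3) and the strongly positive shape are
recovered; θ = σₑ²/σ_β² is the implied ridge regularization ratio; and the
skew-normal model beats the Gaussian baseline by ~62 DIC points on this
strongly skewed replicate. `bsn.predict(X_new)` returns posterior-mean
phenotype predictions β̂₀ + X_newβ̂.

The same analyses run from the shell:

```bash
bsnreg simulate --n 300 --p 500 --rho 0.95 --seed 42 --out-dir data/
bsnreg fit --model bsn --phenotypes data/phenotypes.csv --markers data/markers.csv \
           --iters 10000 --burnin 5000 --seed 1 --out-dir fits/
bsnreg cv  --phenotypes data/phenotypes.csv --markers data/markers.csv \
           --partitions 100 --seed 3 --out-dir cv/
bsnreg mc  --n 300 --p 500 --rho 0.95 --replicates 10 --seed 4 --out-dir mc/
```

Phenotype/marker files are plain CSV (optionally with a shared `id`
column); every output carries a provenance header with version, seed and a
config hash.

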