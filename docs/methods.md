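# Methods

## Model

`bsnreg` fits two Bayesian whole-genome regressions of a phenotype vector
y (length n) on a marker matrix X (n×p, genotype codes in {0,1} or
{0,1,2}, typically p ≫ n):

* **BSN** — residuals follow the centered skew-normal law
  SN_C(0, σₑ², γ₁(ρ)), mean 0 and variance σₑ² by construction, with the
  shape ρ ∈ (−1,1) mapping to the skewness coefficient
  γ₁ = √(2/π) ρ³ (4/π − 1)(1 − 2ρ²/π)^(−3/2), whose attainable range is
  (−0.99527, 0.99527).
* **BRR** — Gaussian residuals; exactly the ρ = 0 submodel, kept as the
  standard genomic-prediction baseline.

Both share the priors β₀ ~ N(0, σ²_{β0}), β ~ N_p(0, σ_β² I),
σₑ² ~ ScaledInvChi2(df_e, S_e), σ_β² ~ ScaledInvChi2(df_b, S_b)
(density ∝ (σ²)^(−df/2−1) e^(−S/2σ²); mode S/(df+2)), and for BSN
ρ = 1 − 2B with B ~ Beta(a₀, b₀). The marker matrix enters uncentered; an
explicit centering step is the caller's choice, not a hidden default.

Assumptions worth stating: residuals are iid (no genotype×environment
structure, no heteroscedasticity); marker effects are exchangeable a
priori (pure ridge shrinkage, no variable selection); and skewness is a
property of the residual law, not of the genetic signal.

## Estimation

The skew-normal residual admits the hidden-truncation representation
(U | Z = z) ~ N(ρz, 1−ρ²) with Z half-normal, which yields an augmented
likelihood that is Gaussian in a working response given the latent z
(constants EU, SU, ζ, and the full conditional algebra are derived in
`derivations.md`). One sampler scan updates
{β₀, β (single-site sweep, ascending), σ_β², z, (ρ, σₑ²)}; ρ and σₑ² have
no closed-form conditionals and use univariate random-walk Metropolis on
the atanh and log scales with Jacobian-corrected acceptance. BRR is
all-Gibbs. The production path is a numba-compiled fused chain
(`_fast.py`); an equivalent pure-numpy path built from the individually
unit-tested kernels (`engine="reference"`) exists for validation, and the
two are compared distributionally in the tests. Truncated-normal draws use
plain rejection near the bulk and a translated-exponential rejection in
the far tail.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_iter`, `burn_in` | 150 000 / 50 000 | long-run analysis protocol (100k retained); experiments and tests use 10k/5k, which recovers scalar posteriors well at n≈300 |
| `thin` | 1 | scalar chains are cheap to keep |
| `sigma2_b0` | 10⁶ | effectively flat, proper intercept prior |
| `df_e`, `df_b` | 5 | weakly informative variance priors |
| `S_e` | 0.5·V_y·(df_e+2) | prior mode of σₑ² at half the phenotypic variance V_y |
| `S_b` | 0.5·V_y·(df_b+2)/MSx | same split for markers, scaled by MSx = n⁻¹ΣΣx²ᵢⱼ |
| `a0`, `b0` | 1, 1 | uniform shape prior on (−1,1); symmetric and weakly informative since no elicitation rule for (a₀,b₀) is established |
| `adapt_target` | 0.23 | classic optimal random-walk acceptance rate |
| `adapt_window` | 100 | batch size for step adaptation (see below) |
| `rho_step`, `sig_step` | 0.1 | initial proposal sd on atanh / log scales |

Initialization: β₀ = ȳ, β = 0, σₑ² = V_y/2, σ_β² = S_b/(df_b+2), ρ = 0,
z = √(2/π) — moment-scale starting values; ρ = 0 starts the chain at the
BRR submodel.

## Numerical choices

* **Step adaptation.** Proposal sds are adapted every `adapt_window`
  iterations during burn-in by Robbins-Monro on the log step
  (gain min(1, max(0.5, 3/√batch))), and the frozen post-burn-in step is
  the Polyak-Ruppert geometric mean of the steps visited over the second
  half of burn-in. The averaging matters: freezing the last iterate leaves
  realized acceptance anywhere in [0.15, 0.29] across seeds, while the
  averaged step keeps it near 0.23 (±0.05). Adaptation stops at burn-in,
  preserving detailed balance for retained draws.
* **Log densities.** The skew-normal log-likelihood uses a stable log Φ
  (asymptotic expansion below −8σ), so strongly skewed fits never produce
  −∞ from tail underflow.
* **γ₁ inversion.** `gamma1_to_rho` clamps requests within 10⁻⁶ of the
  attainable bound 0.99527 before the bracketed root find and rejects
  values at or beyond it.
* **Sample skewness.** γ̂₁ = m₃/s³ with m₃ the n⁻¹ third central moment
  and s the (n−1)-denominator standard deviation; `ddof=0` switches to the
  n-denominator convention.
* **Degenerate inputs.** Constant phenotypes (no variance to elicit
  priors from), non-finite values, monomorphic requested marker columns
  and out-of-support states are rejected with informative errors rather
  than propagated.
* **DIC.** Deviance is −2× the *marginal* (observed-data) log-likelihood;
  pD = D̄ − D(θ̄) with θ̄ the posterior means of (β₀, β, σₑ², ρ). The
  conditional-on-z deviance is deliberately not used because it is not
  comparable between BSN and BRR. pD values depend on this choice.

## Synthetic data

`synth_markers` draws iid Bernoulli(maf) genotypes (Binomial(2, maf) for
SNP coding), resampling monomorphic columns. `simulate_phenotypes`
implements the additive generative model: intercept 3, ten causal effects
drawn N(0, 0.5/10) (placed at the classic wheat-panel positions when
p = 1279, otherwise spread evenly over 1..p, reduced to p effects when
p < 10), residual sd 1.5, and exact centered skew-normal errors
σₑ(U − EU)/SU built from the hidden-truncation sampler, so simulated
errors have mean 0, variance 2.25 and skewness γ₁(ρ) by construction.

What the generator does **not** emulate is linkage disequilibrium: columns
are independent, so the eigenvalue spectrum of XX′ is Marchenko-Pastur
bulk rather than the highly concentrated spectrum of a real DArT/SNP
panel. This matters for one estimand: with iid markers at p ≫ n the
ridge-type prior absorbs part of the residual noise into Xβ (the effective
number of parameters is several hundred rather than the ~60 seen on real
LD-structured panels), so the posterior mean of σₑ² settles around 1.9
when the generative value is 2.25 — verified to be the true posterior by
an independent MCMC implementation, not a sampler artifact. Passing
recovery tests for β₀ and ρ therefore transfer to real data, while the
absolute level of σ̂ₑ² (and of pD, θ) is marker-matrix dependent and
should not be read as an estimate of the generative residual variance in
the iid-marker setting.

## Experiment harnesses and problem sizes

`run_monte_carlo` repeats simulate→fit(BSN, BRR)→summarise with
deterministic per-replicate seeds and records posterior summaries, fit
metrics (Cor(y,ŷ), Cor(β,β̂), Cor(Xβ,Xβ̂), MSE), pD and DIC per replicate;
failures are recorded per row, never dropped. `cross_validate` evaluates
predictive correlation and MSE over seeded random train/test partitions
and counts per-partition wins. The package's standing experiment
configuration — also used by `scripts/acceptance.py` — is n = 300,
p = 500, 10 replicates, 10,000-iteration chains with 5,000 burn-in, a
deliberately scaled-down design whose across-replicate standard errors
are small enough to check recovery of β₀ (≈3), ρ (≈0.94 at ρ=0.95, ≈0.99
at ρ=0.99) and the DIC preference for BSN on strongly skewed data.

## Known limitations

* Marker effects are ridge-only; no BayesA/B/Cπ-style priors.
* ρ mixes slowly on weakly skewed data (|γ₁| small): its posterior is then
  genuinely diffuse and single short chains can wander; the replicated
  harness averages this out, but single-dataset inference on ρ should use
  the long default chains.
* No G-BLUP reparametrization, kernel (RKHS) extension, or multi-
  environment modelling.
* DIC is the only model-comparison criterion implemented (no WAIC/Bayes
  factors).
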