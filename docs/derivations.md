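# Full conditional distributions of the augmented skew-normal regression

This note derives every conditional used by the samplers. Notation:
phenotypes `y` (length n), marker matrix `X` (n x p), linear predictor
`mu_i = beta0 + x_i' beta`, shape `rho` in (-1, 1), residual variance
`s2e = sigma_e^2`, marker-effect variance `s2b = sigma_b^2`, latent
`z_i > 0`. Derived constants:

    EU   = sqrt(2/pi) * rho
    SU   = sqrt(1 - (2/pi) * rho^2)
    zeta = SU / (sigma_e * sqrt(1 - rho^2))
    c    = sigma_e * rho / SU
    d    = sigma_e * EU / SU

## Augmented likelihood

The joint density of one observation and its latent variable is

    f(y_i, z_i) = zeta/sqrt(2 pi) * exp{ -zeta^2/2 (y_i - mu_i - c z_i + d)^2 }
                  * 2/sqrt(2 pi) * exp{ -z_i^2/2 } * 1(z_i > 0),

so the complete-data log-likelihood is

    L(theta, z) = sum_i [ log zeta - log pi
                          - zeta^2/2 (y_i - mu_i - c z_i + d)^2 - z_i^2/2 ].

Given z, define the working response `w_i = y_i - c z_i + d`; then L is a
Gaussian regression log-likelihood in w with homoscedastic precision
`zeta^2`. All location-parameter conditionals follow by conjugacy.

## Priors

    beta0 ~ N(0, s2b0)
    beta  ~ N_p(0, s2b I)
    s2e   ~ ScaledInvChi2(df_e, S_e)     density  prop. (s2e)^-(df_e/2+1) e^{-S_e/(2 s2e)}
    s2b   ~ ScaledInvChi2(df_b, S_b)
    rho = 1 - 2B,  B ~ Beta(a0, b0)  =>  p(rho) prop. (1-rho)^(a0-1) (1+rho)^(b0-1) on (-1,1)

## beta0 | rest

Quadratic in beta0:  -zeta^2/2 sum_i (w_i - x_i'beta - beta0)^2 - beta0^2/(2 s2b0).
Completing the square:

    beta0 | rest ~ N( zeta^2 * sum_i (w_i - x_i'beta) / P ,  1/P ),
    P = n * zeta^2 + 1/s2b0.

## beta_j | rest (single-site)

With partial residual `r_i^(j) = w_i - beta0 - sum_{k != j} x_ik beta_k`:

    beta_j | rest ~ N( c_j/d_j , 1/d_j ),
    d_j = zeta^2 * sum_i x_ij^2 + 1/s2b,
    c_j = zeta^2 * sum_i x_ij r_i^(j).

Sweep order is ascending j, fixed.

## s2b | rest

Prior kernel (s2b)^-(df_b/2+1) e^{-S_b/(2 s2b)} times likelihood
(s2b)^(-p/2) e^{-beta'beta/(2 s2b)} gives

    s2b | rest ~ ScaledInvChi2( df_b + p , S_b + beta'beta ).

Sampling: (S_b + beta'beta) / chi2_{df_b + p}.

## z_i | rest

Collect z_i terms with `a_i = y_i - mu_i + d`:

    -zeta^2/2 (a_i - c z_i)^2 - z_i^2/2
      = -(1 + zeta^2 c^2)/2 * ( z_i - m_i )^2 / 1 + const,

so with `v = 1/(1 + zeta^2 c^2)` and `m_i = v * zeta^2 * c * a_i`,

    z_i | rest ~ TN( m_i , v , 0, inf ).

Because zeta^2 c^2 = rho^2/(1-rho^2), v simplifies to 1 - rho^2 and
m_i = rho * SU * a_i / sigma_e; the generic (m, v) form is implemented and
the simplification is exercised by tests. At rho = 0 the conditional is the
half-normal TN(0, 1, 0, inf): the latent layer decouples from the data.

## (rho, s2e) | rest

No closed form: rho and s2e enter through zeta, c and d both inside and
outside the exponent. The conditional kernel is

    g(rho, s2e) = n log zeta - zeta^2/2 sum_i (y_i - mu_i - c z_i + d)^2
                  + (a0-1) log(1-rho) + (b0-1) log(1+rho)
                  - (df_e/2 + 1) log s2e - S_e/(2 s2e).

Each is updated by univariate random-walk Metropolis on a transformed
scale: `t = atanh(rho)` with Jacobian `drho/dt = 1 - rho^2`, and
`u = log s2e` with Jacobian `s2e`. Acceptance ratio for rho:

    min{1, exp[ g(rho', s2e) + log(1-rho'^2) - g(rho, s2e) - log(1-rho^2) ]},

and analogously with `+ log s2e` for the variance. Proposal standard
deviations are adapted in batches during burn-in toward acceptance 0.23 and
frozen afterwards, so the post-burn-in kernel satisfies detailed balance.

## Gaussian (ridge) special case

At rho = 0: zeta = 1/sigma_e, c = d = 0, so the working response is y
itself, and the z layer integrates out of everything. s2e then has the
conjugate update

    s2e | rest ~ ScaledInvChi2( df_e + n , S_e + e'e ),   e = y - beta0 - X beta,

which together with the beta0/beta/s2b updates above is the standard
Bayesian ridge Gibbs sampler.

## Marginal (observed-data) likelihood

Integrating z out of the augmented density returns the centered
skew-normal density; equivalently, with omega = sigma_e/SU,
xi = mu - omega*EU and lam = rho/sqrt(1-rho^2),

    log f(y_i) = log 2 - log omega + log phi((y_i - xi)/omega)
                 + log Phi(lam (y_i - xi)/omega).

This is the likelihood entering the deviance, pD and DIC.
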