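# Methods

## The problem

Paired RNA-Seq designs — tumor and matched normal from the same patient,
before/after treatment on the same subject — produce correlated count pairs.
Power calculations that assume independent samples misstate both the type-I
error and the power of differential-expression tests on such data.  This
package estimates power and actual false positive rates for paired designs by
direct Monte Carlo simulation, because the finite-sample null distributions of
the relevant test statistics have no usable closed form.

## Models

### Bivariate negative binomial (BNB)

Counts for subject i under the two conditions are modelled as a Poisson-Gamma
compound with a shared subject effect:

    G_i ~ Gamma(shape 1/phi, scale phi)          E[G]=1, Var[G]=phi
    X_i | G_i ~ Poisson(mu * G_i)
    Y_i | G_i ~ Poisson(gamma * mu * G_i)

Marginally X ~ NB(mean mu, variance mu + phi mu^2), and the shared effect
induces Cov(X, Y) = gamma phi mu^2.  The joint pmf is

    P(x, y) = phi^(-1/phi)/Gamma(1/phi) * mu^x (gamma mu)^y / (x! y!)
              * Gamma(x+y+1/phi) / (mu + gamma mu + 1/phi)^(x+y+1/phi)

Differential expression is gamma != 1, tested against H0: gamma = gamma0
(default 1) by

* **LRT**: 2 (l_full − l_constrained), referenced to chi-square(1);
* **Wald**: (gamma_hat − gamma0)^2 / v_hat, where v_hat is the variance of
  gamma_hat implied by the observed information (central-difference Hessian of
  the negative log-likelihood in log-parameters, step 1e-4) evaluated at the
  **null-constrained** MLE and mapped to the gamma scale.

The Wald form deserves a note, because the choice of scale and evaluation
point is not innocuous in finite samples.  A Wald statistic standardized by
the information at the *full* MLE on the *log* scale is numerically almost
identical to the LRT here (the likelihood factorizes, see below, and all
information estimators for log gamma agree), so it reproduces neither of the
two characteristic finite-sample behaviors of the Wald test in this setting:
an upper null tail well above chi-square(1) at small mean expression, and
power that is higher than the LRT for up-regulation but lower for
down-regulation.  The gamma-scale, null-standardized form has both: the right
skew of gamma_hat inflates the extreme upper tail while the bulk still tracks
chi-square, and the gamma-scale distance to the null is bounded by gamma0 on
the down side.  Asymptotically all forms are equivalent.  Because this
statistic is *not* chi-square calibrated, it must be used with empirical
critical values (below); that combination controls the false positive rate
exactly as well as the LRT does.

**Useful structure.** Conditional on the totals s_i = x_i + y_i, the y_i are
Binomial(s_i, gamma/(1+gamma)) and the s_i are NB(mu(1+gamma), phi).  Hence
the free-gamma MLE is gamma_hat = sum(y)/sum(x) in closed form, and the
information about log gamma under the null is S/4 with S the grand total.
The implementation does **not** use this shortcut — it maximizes the full
likelihood numerically, exactly as the constrained fits must — but the test
suite uses it as a decisive independent oracle for the optimizer.

### Poisson-LMM and NB-LMM

The mixed-model route conditions on a Gaussian subject intercept instead of a
Gamma one:

    count_ij | b_i ~ Family(mean exp(beta0 + beta1 c_ij + offset_ij + b_i))
    b_i ~ Normal(0, sigma2)

with Family either Poisson or NB (conditional variance m + phi m^2), c_ij the
condition indicator, beta1 the log fold ratio.  H0: beta1 = 0 is tested by
LRT.  Wald statistics under these models are exposed only behind a
`diagnostics=True` flag: their null behavior is numerically unstable and far
from chi-square, and they are not offered for power analysis.

The marginal likelihood integrates b out by **adaptive Gauss–Hermite
quadrature** (default 25 nodes): per subject the integrand is re-centred at
the conditional mode of b — found by damped Newton iteration, globally
convergent because the integrand is log-concave in b — and scaled by the
Laplace curvature.  Quadrature results are deterministic; on the grids used
here, doubling the node count changes the log-likelihood by < 1e-9, and a
400,001-point trapezoid integration agrees to 1e-8.  sigma2 = 0 reduces
exactly to the fixed-effects GLM likelihood, which is the second oracle.

## The empirical parametric test and the six-step procedure

For one scenario (n, mu, gamma, phi, alpha, T, test):

1. fix the inputs;
2. simulate T null datasets from BNB(mu, 1, phi) and T alternative datasets
   from BNB(mu, gamma, phi), n pairs each;
3. compute the statistic on every null dataset;
4. take the 100(1−alpha)th percentile of the null statistics as the critical
   value (or the chi-square(1) upper-alpha quantile);
5. compute the statistic on every alternative dataset;
6. power = fraction of alternative statistics strictly exceeding the critical
   value, with binomial standard error sqrt(p(1−p)/retained).

All four tests are always *applied to BNB-generated data* — the GLMM tests
are evaluated as a practitioner would apply them to real paired counts whose
true generating mechanism is not Gaussian-intercept.

Design choices within this procedure:

* **Percentile convention**: linear interpolation with the k-th order
  statistic at probability (k−1)/(N−1) (`numpy.percentile` default).  At
  T = 20,000 and alpha >= 0.0005 the convention is immaterial, but
  determinism requires fixing one.
* **Independent evaluation replication**: when an *actual FPR* of the
  empirical test is reported, the critical value comes from one null
  replication and the rejection rate from a second one with a fresh seed;
  evaluating on the defining draws would return alpha tautologically.  Output
  metadata records this.
* **Null sharing**: within a grid, the null statistic bag is shared across
  gamma values of the same (n, mu, phi, test) cell; the null hypothesis is
  always gamma0 = 1, also for down-regulated alternatives.
* **Ties**: rejection requires the statistic to strictly exceed the critical
  value (the conservative reading of an upper-percentile threshold).
* **Failures**: non-convergent fits and non-identifiable datasets (all counts
  zero — common at phi = 100 with small mu·n) are excluded from the statistic
  bag, never imputed; their count travels with every result, and a run whose
  failure fraction exceeds 1% carries a recorded warning.
* **Negative NB-LMM LRTs** are retained unclamped (and counted): the
  NB-LMM null fit can genuinely beat the full fit on the extremely flat
  sigma2/phi ridge, and clamping would distort the conservative shape of its
  empirical null.  Poisson-family LRTs below −1e-6 after a warm-started
  refit raise an error instead, since strict nesting holds there.
* **Seeding**: a master seed is hashed (SHA-256) with scenario labels into a
  31-bit cell seed; each cell spawns one `SeedSequence` substream per
  replicate.  Cells are pure functions of (scenario, seed): any execution
  order, chunking or `joblib` scheduler yields bit-identical tables.

## Numerical notes

* **Optimization** is L-BFGS-B on log-transformed positive parameters
  (|log param| <= 30) with analytic gradients: closed-form for the BNB, via
  the Fisher identity (posterior node-weighted complete-data score) for the
  quadrature likelihood.  Starting values: moment estimates (BNB), the
  sigma2 = 0 GLM solution (GLMMs).
* **phi -> 0 limit**: for 1/phi > 1e6 the exact likelihood subtracts
  gammaln terms of order 1e9+ and loses the digits the optimizer needs, so
  both likelihoods switch to the Poisson limit plus the first-order 1/phi
  correction (the phi-score there is the half-difference between the
  variance and the mean).  Without this branch ~1.5% of small-n fits failed
  in line search near the boundary.
* **Boundary handling**: sigma2 is searched on the log scale with a floor at
  1e-10; fits ending below 1e-6 are flagged as boundary solutions (the
  profile is numerically flat on that ray) rather than rejected.  Datasets
  with sum(x) = 0 xor sum(y) = 0 put gamma_hat on the boundary and are
  flagged; the Wald statistic is unavailable there and counts as a failure.
* **Convergence fallbacks**: a line-search abort at a point whose projected
  gradient is already small is accepted as converged; GLMM fits additionally
  get a short Nelder–Mead polish, because the NB-LMM sigma2/phi ridge is
  flat enough to defeat curvature-based stopping rules.

### Lattice atoms in the extreme tail

Both BNB statistics are (for the LRT: exactly, by the factorization above)
functions of the two condition totals (sum x, sum y) alone.  Those totals are
integers and, through the shared subject effects, strongly correlated (rho
~0.9 at mu = 10, phi = 1, n = 10), so the statistic's null distribution is
discrete with point masses that in the extreme tail reach ~1e-4 — a tenth of
alpha = 0.001.  Two consequences worth knowing: the 99.9th-percentile
critical value estimated from T = 20,000 draws can sit below or above a
specific atom cluster depending on the seed, and the actual FPR of the
empirical parametric test measured on an independent replication then
fluctuates somewhat beyond its binomial standard error for unlucky seeds
(measured across eight master seeds: mean 0.0009, sd 0.0002 for the Wald
statistic at the scenario above, with occasional larger excursions).  This
is a property of the procedure on discrete data, not of the implementation;
averaging over seeds or raising T tightens it.

## What the synthetic data does and does not emulate

The generator *is* the model: BNB draws at specified (n, mu, gamma, phi), and
for the pilot-study fixture a genes × pairs matrix with per-gene parameters
drawn from lognormal laws (mu median 50, phi median 0.2, gamma median 1)
chosen to resemble the percentile spread of a tumor/matched-normal cohort.
Real data depart from this in ways the simulations do not probe: library-size
variation beyond a fixed per-sample offset, gene–gene correlation, unequal
dispersion between conditions, and count noise that is not Poisson-Gamma.
Passing tests therefore certify the *procedure* — calibration, error control,
ordering of tests — under the stated generating model, not the adequacy of
that model for any particular dataset.  Normalized pilot counts are rounded
to integers before fitting (the pmf lives on integers); the number of cells
changed by rounding is reported.

## Problem sizes used by the shipped checks

BNB-based checks run at the production simulation counts (T = 20,000 for
calibration/FPR, T = 5,000 per hypothesis for the design-point powers).  The
mixed-model checks are scaled to keep a serial run practical: T = 2,000
(alpha = 0.01) for the GLMM FPR checks, and T = 300 per hypothesis for the
GLMM cells of the reduced power grid (BNB cells: T = 1,000), with every
statistical tolerance computed from the Monte Carlo standard errors of the
sizes actually run.  A full 4-test × 5^4 grid at T = 20,000 is a
multi-day serial computation; `power_grid(..., n_jobs=-1)` parallelises it
cell-wise without changing any number.

## Known limitations

* Equal dispersion across conditions is assumed throughout.
* Only the paired two-condition design is implemented for the GLMMs: one
  condition fixed effect, one subject random intercept.  General design
  matrices, multiple random effects and random-effect tests are out of scope.
* Power is per-gene (per-comparison error rate); data-set-level power across
  gene groups is not computed.  Multiplicity enters only through the choice
  of alpha.
* TMM or other normalization is external: the pilot fitter accepts
  per-sample log offsets and records the rounding it then performs.
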