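# Methods

## Scope and models

`snpblup` studies the effect of allele coding on genomic evaluation in two
equivalent Gaussian models at fixed or estimated variance components:

* **Marker model (SNP-BLUP).** y = 1μ + Zg + e with g ~ N(0, I σ²g) and
  e ~ N(0, I σ²e).  The residual covariance is always I σ²e; more general R
  is out of scope (several centered-coding results hold only for scaled-
  identity R).  Only the Gaussian ("ridge") marker prior is implemented;
  heavy-tailed per-marker priors are out of scope, although the coding-
  invariance argument (which integrates the general mean out) does not
  depend on the prior.
* **Equivalent model (GBLUP).** a = Zg with a ~ N(0, G σ²a),
  G = ZZ′/(2Σp(1−p)) and σ²a = 2Σp(1−p)·σ²g, frequencies p observed in the
  data being analyzed.  Base-population frequencies, adjusted or extended
  (single-step) relationship matrices are out of scope.

Allele codings are the shift family Z = Z0 − 1v′ (012, 101, centered,
arbitrary v) plus the allele swap 210 = 2 − Z0.  `Z0` always counts the
allele that is *less frequent in the data*; columns tied at frequency 0.5
keep their incoming orientation, and the flip mask is stored so a run is
reproducible.

## Synthetic populations

The simulator emulates a workshop-style dataset: a factorial mating design
(s sires per generation, each mated to a fixed number of dams, each mating
producing a fixed number of progeny) over discrete generations; at the
paper-scale default (15 × 10 × 10, 4 generations) this gives 165 + 3×1500 =
4665 animals with 6000 equally spaced markers on 6 chromosomes of 1 morgan.
Parents are selected at random — there is no selection on the trait — and
every animal is genotyped and phenotyped.

Genotypes are gene-dropped: founder haplotypes are Bernoulli(p₀) per locus
with p₀ ~ U(0.05, 0.5) by default (configurable; the band keeps attrition
at the 1% MAF filter small), and each non-founder receives one recombinant
gamete per parent with Haldane switch probability r = (1 − e^{−2d})/2
between adjacent markers.  Offspring sex is a balanced 1:1 split in random
order rather than independent coin flips, so any design whose generation
size is at least twice the required parents of each sex is always feasible;
with fair coins, small designs would fail stochastically for no scientific
reason.  The phenotype is assembled as y = 1μ + Z0 g_true + e and the
components are stored, so the decomposition holds to machine precision.
When a target h² is requested, σ²e is rescaled so that
2Σp(1−p)σ²g / (2Σp(1−p)σ²g + σ²e) equals the target using the *observed*
frequencies of the analyzed panel.  For this reason the pipeline applies
the MAF filter to the genotypes *before* drawing phenotypes: effects at
discarded markers would otherwise act as a small extra residual and bias
heritability recovery low.

Default study scale is 505 animals (5 × 10 × 3 design — the closest the
factorial design comes to 500) × 600 markers, chosen so the complete study
runs in minutes on one CPU; the full 4665 × 6000 scale remains configurable.

## Mixed-model equations and uncertainty

The marker MME coefficient matrix is the (1+m)×(1+m) Henderson system
[[n/σ²e, 1′Z/σ²e], [Z′1/σ²e, Z′Z/σ²e + I/σ²g]].  Its full inverse yields
Var(μ|y), Cov(μ, g|y) and C_g = Var(g|y); PEV via the marker route is
diag(Z C_g Z′), and Var(â_d|y) is the sandwich
1c^{μμ}1′ + 1c^{μg}′Z′ + Zc^{μg}1′ + ZC_gZ′.  The GBLUP MME
[[n/σ²e, 1′/σ²e], [1/σ²e, I/σ²e + G⁻¹/σ²a]] gives â, PEV as the inverse's
breeding-value diagonal, and reliability 1 − PEV/(Gᵢᵢσ²a).  The
reliability denominator uses the *raw* (pre-inflation) diagonal by default,
with a flag to use the inflated one.  All linear algebra is dense
(Cholesky); the package targets desk scale (n, m ≲ 5000) and deliberately
has no sparse or iterative path.

G is singular whenever rank(Z) < n — always for the centered coding (its
column sums vanish, so G1 = 0), with duplicate genotypes, and whenever
m < n.  The implemented remedy is the study's: multiply the diagonal by
1.001 (configurable).  The non-inverted MME formulation is a non-goal.

## REML

The restricted log-likelihood is evaluated in error-contrast form with
V = ZZ′σ²g + Iσ²e (marker) or Gσ²a + Iσ²e (GBLUP):
lR = −½[(n−1)log2π + log|V| + log(1′V⁻¹1) − log n + y′Py].  The constant is
fixed so the value equals the log-density of K y for any orthonormal
contrast basis orthogonal to 1, which makes the two model forms agree
exactly when ZZ′σ²g = Gσ²a and lets an independent contrast-matrix oracle
check the implementation.

Two optimizers, both stopping when the maximum relative parameter change
drops below 1e-8 (EM capped at 500 iterations, AI at 50):

* **EM-REML** from the MME inverse: σ²g ← (ĝ′ĝ + tr C_g)/m,
  σ²e ← y′(y − 1μ̂ − Zĝ)/(n − 1) (and the G⁻¹-weighted analogue for GBLUP).
  Monotone in lR but linearly convergent; near a flat optimum (weak
  per-marker signal) it can need thousands of iterations, which is why the
  unit tests compare EM to AI on well-identified fixtures.
* **AI-REML**: Newton steps with the average-information matrix
  ½y′PKᵢPKⱼPy; any step proposing a non-positive variance falls back to the
  equivalent P-form EM update for that round.

Iteration counts are reported for the convergence comparison across codings
and models but never asserted against external software's counts: they
depend on the convergence criterion, which differs between implementations.

## Gibbs sampling

Single-site (the stochastic Gauss–Seidel) and block samplers for
(μ, g, σ²g, σ²e), update order μ, g₁…g_m (or the g block via a dense
Cholesky draw), σ²g, σ²e — fixed for reproducibility; one seeded PCG64
stream per chain; every chain is bitwise reproducible.  Variance priors are
scaled-inverse-chi-square with ν = −2, s² = 0 by default (flat on the
variance scale, proper posterior given data) and configurable; μ has the
flat improper prior that the invariance theory assumes.  Chains can be run
with variances fixed, targeting the Gaussian [μ, g | y] to which the
convergence-rate theory applies exactly.  Defaults mirror the study's chain
shape (burn-in then thinning to every 10th sample).

ESS uses the initial monotone sequence estimator: pair sums
Γⱼ = γ₂ⱼ + γ₂ⱼ₊₁ of empirical autocovariances are truncated at the first
non-positive pair and monotonized by running minimum;
τ = (−γ₀ + 2ΣΓⱼ)/γ₀ and ESS = min(N, N/τ).  Anti-correlated chains (τ < 1)
are capped at N; constant sequences return NaN ("undefined") rather than
propagating silently.  Against a stationary AR(1) with φ = 0.9 the
estimator agrees with the closed form N(1−φ)/(1+φ) to well within 20% at
N = 9000, and with an independent Geyer implementation to ~1%.

## Convergence-rate theory

For a Gaussian target with precision Q split into ordered blocks, the Gibbs
sweep converges at rate ρ = max-modulus eigenvalue of B = (I − L)⁻¹U with
Aᵢⱼ = −(Qᵢᵢ)⁻¹Qᵢⱼ, L the block lower triangle, U = A − L.  This generic
recipe is the implementation; two identities serve as independent oracles
in the tests rather than as formulas: the two-block rate equals the
rank-one quadratic form v′Cv (the μ–g cross block has rank one), and the
single-site rate equals the spectral radius of the Gauss–Seidel iteration
matrix of Q.  Rates below 1e-12 are snapped to exactly 0 in reports (the
centered two-block rate is an exact zero of the theory, reached to ~1e-31
numerically).  Relative mixing is k = log(ρ_ref)/log(ρ); k = 0 is reported
for ρ = 0 (instant mixing) and k is undefined at ρ = 1.

Two empirical connections are verified: for the two-block sampler the
μ-marginal chain is AR(1) with lag-1 autocorrelation equal to ρ₁ (and ≈ 0
under centered coding); for the single-site sweep the full autocovariance
curve of μ matches Cov(x_{t+k}, x_t) = BᵏΣ.  The lag-1 autocorrelation of a
*single coordinate* under single-site updating generally exceeds ρ₂ at
small lag — ρ₂ governs the asymptotic decay — so the exact lag-1 identity
is asserted for the two-block scheme and the single-site check uses the
BᵏΣ curve.

Convergence rates in the study report are computed at the variance
components estimated by the centered single-site Gibbs chain when the Gibbs
stage ran, else at the simulation values.

## Study pipeline and invariance battery

`run_study` chains simulation, MAF filter, per-scheme coding, Gibbs,
convergence theory, REML (both models, EM and/or AI) and GBLUP
reliabilities into one seeded, logged run that writes the seven comparison
tables (posterior means, ESS, rates, REML iterations, REML estimates,
reliability summaries, reliability correlations).  `validate_invariance`
then asserts, machine-readably, that marker effects (sign-flipped for 210),
complete GEBVs, marker-model REML estimates and posterior variance
components agree across codings — and that μ, PEV, reliabilities and ρ
genuinely differ.  Posterior agreement is judged against Monte-Carlo
standard-error bands from the chains' own ESS.

## What the simulations do and do not show

The generator reproduces the *structural* features the theory needs —
family structure, linkage, a polygenic trait with chosen h², m ≷ n regimes —
but not real-data features such as selection, non-random mating, missing
genotypes, low-MAF-enriched frequency spectra or QTL sparsity.  Exact
invariance results (BLUP, REML, complete GEBVs, Var(â_d|y)) are
data-distribution-free, so passing them on synthetic data is conclusive up
to floating-point error.  Pattern results (ESS and reliability orderings
across codings) are data-bound: the extremes (centered best, 210 worst) are
robust at desk scale, but the middle of the ordering (012 vs 101) depends
on the allele-frequency spectrum and sample size — at very small scale it
can genuinely invert, which the test suite handles by checking the strict
four-way ESS ordering only at a scale where the exact integrated
autocorrelation times are strictly ordered, with fixed-variance chains
(the rate theory's setting).

## Numerical choices

* Dense Cholesky/inverse everywhere; MME solved in covariance (1/σ²e)
  scaling so the inverse directly gives posterior covariances.
* Diagonal inflation default 1.001; GBLUP refuses near-singular G
  (condition number > 1e12) with guidance to inflate.
* MAF filter is strict (`p < threshold` removed), so p = 0.01 survives at
  the 1% threshold.
* Tie-break at p = 0.5: keep incoming orientation, record the flip mask.
* Convergence tolerances: REML 1e-8 relative parameter change; coded-matrix
  centering exact to ~1e-10·n; rate snap-to-zero at 1e-12.
* Monte-Carlo test sizes: unit fixtures 87–355 animals × 39–150 markers;
  replicate experiments at the 505 × 600 study scale.  Statistical
  assertions use MC standard-error bands derived from ESS, not fixed
  constants, wherever a quantity is stochastic.

## Known limitations

Single trait, single genomic random effect, identity residual covariance;
no missing genotypes or imputation; no BayesA/B-style per-marker variances;
no convergence theory for the variance updates (rates are for [μ, g | y] at
fixed variances); dense algebra only.  REML iteration counts are
comparable across codings within this implementation but not to other
software.
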