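# snpblup — allele coding in genomic evaluation

Genomic prediction regresses phenotypes on thousands of SNP markers at once.
Before anything is estimated, each biallelic genotype must be turned into a
number: 0/1/2 copies of an allele, −1/0/1, or a mean-centered value.  This
*allele coding* choice looks cosmetic — and for most inferences it is — but
it changes the genomic relationship matrix, prediction error variances,
published reliabilities, and the mixing of MCMC samplers.  `snpblup` is a
small library for quantitative geneticists that makes every one of these
effects directly computable on simulated breeding populations.

## The model

The marker-based model (SNP-BLUP) is

    y = 1 μ + Z g + e,    g ~ N(0, I σ²g),    e ~ N(0, I σ²e)

with `Z` (n × m) the coded design matrix.  All codings considered are either
shifts of the unique minor-allele-count matrix `Z0`,

    Z = Z0 − 1ₙ v′        (012: v = 0;  101: v = 1;  centered: v = 2p),

or the allele swap `Z = 2·11′ − Z0` (210).  The equivalent GBLUP model works
with breeding values `a = Z g`, `a ~ N(0, G σ²a)`, where

    G = Z Z′ / (2 Σⱼ pⱼ(1 − pⱼ)),    σ²a = 2 Σⱼ pⱼ(1 − pⱼ) σ²g.

What the package demonstrates by computation, on populations it simulates by
gene dropping through a factorial mating pedigree:

* **Invariant to coding** (given a fixed general mean): marker-effect BLUPs
  ĝ and their posterior covariance, complete breeding values
  â_d = 1μ̂ + Zĝ, REML variance components, Bayesian posteriors of
  (g, σ²g, σ²e), and Var(â_d | y).
* **Not invariant**: the general mean (shifts by exactly v′ĝ), PEV and
  reliabilities r²ᵢ = 1 − PEVᵢ/(Gᵢᵢ σ²a), effective sample sizes of Gibbs
  chains, and the theoretical convergence rates ρ = max-modulus eigenvalue
  of B = (I − L)⁻¹U built from the posterior precision of [μ, g | y].  The
  centered coding zeroes the μ–g coupling, making the two-block Gibbs
  sampler exact Monte Carlo (ρ₁ = 0).

## Worked example

`examples/02_coding_invariance.py` simulates 505 animals × ~600 markers
(h² = 0.30), fits the SNP-BLUP equations under four codings and prints:

```
scheme    mu_hat   max|g_hat - g_hat(012)|   corr(g_hat, g_hat(012))
012        1.9141                  0.00e+00           1.0000000000
210        0.8573                  8.08e-15           1.0000000000
101        1.3857                  3.60e-15           1.0000000000
centered   1.5034                  3.38e-15           1.0000000000

mean-shift law: mu(101) - mu(012) = -0.528415 vs v'g_hat = -0.528415
complete GEBVs, max |012 - centered| = 9.19e-14
```

The marker effects are numerically identical in every coding (210 returns
−ĝ because it counts the opposite allele), while the estimated general mean
moves by exactly v′ĝ, so the complete breeding values agree to machine
precision.  The other scripts in `examples/` show, one capability each, the
simulator, reliability divergence between codings, Gibbs mixing (ESS of μ
ranges from ~40 under 210 coding to ~8900 under centered for the same 9000
saved samples), theoretical convergence rates, REML, and the end-to-end
study with its automated invariance battery.

A thin CLI wraps the same functions:
`snpblup simulate|code|blup|reml|gibbs|convergence|study|validate`.

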