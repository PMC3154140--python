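"""Allele coding changes how well the Gibbs sampler mixes.

Runs the single-site sampler for (mu, g, sigma2_g, sigma2_e) under each
coding with a shared seed and compares effective sample sizes (initial
monotone sequence estimator).  Scaled down to ~200 animals x 60 markers so
it finishes in about a minute.
"""

import snpblup as sb

design = sb.BreedingDesign(n_sires_per_gen=4, dams_per_sire=4,
                           progeny_per_mating=3, n_generations=4,
                           n_chromosomes=3, markers_per_chromosome=20)
ped = sb.simulate_pedigree(design, seed=1)
geno = sb.maf_filter(sb.simulate_genotypes(ped, design, seed=2), 0.01)
study = sb.simulate_phenotypes(
    geno, sb.TraitArchitecture(sigma2_g=2e-2, target_h2=0.30), seed=3,
    pedigree=ped)
vc = sb.VarianceComponents.from_marker(study.arch.sigma2_g,
                                       study.arch.sigma2_e, geno)

chains = {}
for s in ("012", "210", "101", "centered"):
    cfg = sb.GibbsConfig(n_iter=20000, burn_in=2000, thin=2, seed=7)
    chains[s] = sb.run_gibbs(study.phenotypes, sb.apply_coding(geno, s), cfg,
                             start=vc)

print("effective sample sizes (9000 saved samples):")
print(sb.mixing_comparison(chains).round(0))
print("\nposterior means:")
for s, ch in chains.items():
    pm = ch.posterior_means()
    print(f"  {s:9s} mu = {pm['mu']:.3f}  sigma2_g = {pm['sigma2_g']:.5f}  "
          f"sigma2_e = {pm['sigma2_e']:.3f}")
# The variance posteriors agree across codings; mu differs by v'E(g|y).  The
# centered coding mixes mu dramatically better because it makes mu and g
# a posteriori independent; 210 mixes worst.
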