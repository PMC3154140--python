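import numpy as np
import pytest

import snpblup as sb


@pytest.fixture(scope="session")
def small_study():
    """A small simulated population (87 animals, ~146 markers, m > n not needed).

    Marker variance is raised to 1e-2 so the genetic signal is visible at
    this scale; h2 is rescaled to 0.30 as in the full design.
    """
    design = sb.BreedingDesign(n_sires_per_gen=3, dams_per_sire=4,
                               progeny_per_mating=2, n_generations=4,
                               n_chromosomes=3, markers_per_chromosome=50)
    ped = sb.simulate_pedigree(design, 11)
    geno = sb.maf_filter(sb.simulate_genotypes(ped, design, 12), 0.01)
    study = sb.simulate_phenotypes(
        geno, sb.TraitArchitecture(mu_true=1.0, sigma2_g=1e-2, target_h2=0.30),
        13, pedigree=ped)
    vc = sb.VarianceComponents.from_marker(study.arch.sigma2_g,
                                           study.arch.sigma2_e, geno)
    designs = {s: sb.apply_coding(geno, s)
               for s in ("012", "210", "101", "centered")}
    return {"design": design, "ped": ped, "geno": geno, "study": study,
            "y": study.phenotypes, "vc": vc, "designs": designs}


@pytest.fixture(scope="session")
def small_fits(small_study):
    y, vc = small_study["y"], small_study["vc"]
    return {s: sb.solve_marker_mme(y, d, vc)
            for s, d in small_study["designs"].items()}


@pytest.fixture(scope="session")
def tiny_study():
    """An even smaller population for MCMC tests (87 animals, ~39 markers)."""
    design = sb.BreedingDesign(n_sires_per_gen=3, dams_per_sire=4,
                               progeny_per_mating=2, n_generations=4,
                               n_chromosomes=2, markers_per_chromosome=20)
    ped = sb.simulate_pedigree(design, 21)
    geno = sb.maf_filter(sb.simulate_genotypes(ped, design, 22), 0.01)
    study = sb.simulate_phenotypes(
        geno, sb.TraitArchitecture(mu_true=1.0, sigma2_g=5e-2, target_h2=0.30),
        23, pedigree=ped)
    vc = sb.VarianceComponents.from_marker(study.arch.sigma2_g,
                                           study.arch.sigma2_e, geno)
    designs = {s: sb.apply_coding(geno, s)
               for s in ("012", "210", "101", "centered")}
    return {"design": design, "ped": ped, "geno": geno, "study": study,
            "y": study.phenotypes, "vc": vc, "designs": designs}


@pytest.fixture()
def toy():
    """The worked 3-animal, 2-marker example used across modules."""
    Z0 = np.array([[0, 1], [1, 0], [2, 1]])
    g = sb.orient_to_minor(Z0)
    y = np.array([1.0, 2.0, 3.0])
    return {"geno": g, "y": y, "vc": sb.VarianceComponents.from_marker(1.0, 1.0, g)}
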