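"""Simulated multi-generation breeding population.

Emulates the structure of a workshop-style genomic-evaluation dataset: a
factorial mating design (s sires each mated to a fixed number of dams, each
mating producing a fixed number of progeny) run for several discrete
generations, biallelic SNPs equally spaced along chromosomes, and a single
additive quantitative trait

    y = 1*mu + Z0*g + e,   g_j ~ N(0, sigma2_g),  e_i ~ N(0, sigma2_e).

Genotypes are produced by gene dropping: founders draw two allele copies per
locus from the founder allele frequency, and every non-founder receives one
gamete per parent with recombination between adjacent markers at the Haldane
probability r = (1 - exp(-2d))/2 for map distance d morgans.

At the default paper-scale design (15 sires x 10 dams x 10 progeny over 4
generations, 6 chromosomes x 1000 markers) the population has
165 + 3*1500 = 4665 animals and 6000 markers.  ``desk_scale_design`` gives a
505-animal / 600-marker version with the same shape for fast experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .coding import GenotypeMatrix, orient_to_minor


@dataclass
class BreedingDesign:
    n_sires_per_gen: int = 15
    dams_per_sire: int = 10
    progeny_per_mating: int = 10
    n_generations: int = 4
    n_chromosomes: int = 6
    markers_per_chromosome: int = 1000
    chromosome_length: float = 1.0  # morgans
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_sires_per_gen", "dams_per_sire", "progeny_per_mating",
                     "n_generations", "n_chromosomes", "markers_per_chromosome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be > 0")
        if not (0.0 <= self.founder_maf_low <= self.founder_maf_high <= 0.5):
            raise ValueError("founder MAF bounds must satisfy 0 <= low <= high <= 0.5")

    @property
    def n_dams_per_gen(self) -> int:
        return self.n_sires_per_gen * self.dams_per_sire

    @property
    def n_founders(self) -> int:
        return self.n_sires_per_gen + self.n_dams_per_gen

    @property
    def progeny_per_gen(self) -> int:
        return self.n_dams_per_gen * self.progeny_per_mating

    @property
    def n_animals(self) -> int:
        return self.n_founders + (self.n_generations - 1) * self.progeny_per_gen

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


def desk_scale_design(**overrides) -> BreedingDesign:
    """A 505-animal, 600-marker design with the paper-scale shape."""
    kwargs = dict(n_sires_per_gen=5, dams_per_sire=10, progeny_per_mating=3,
                  n_generations=4, n_chromosomes=6, markers_per_chromosome=100)
    kwargs.update(overrides)
    return BreedingDesign(**kwargs)


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree; parent id 0 means unknown (founder)."""

    animal_id: np.ndarray
    sire_id: np.ndarray
    dam_id: np.ndarray
    generation: np.ndarray  # 1-based
    sex: np.ndarray  # 'M'/'F', used only for mating-role assignment

    def __post_init__(self) -> None:
        ids = self.animal_id
        if len(np.unique(ids)) != len(ids):
            raise ValueError("animal ids must be unique")
        pos = {a: i for i, a in enumerate(ids)}
        for parent in (self.sire_id, self.dam_id):
            for child_idx, pid in enumerate(parent):
                if pid != 0 and pos[pid] >= child_idx:
                    raise ValueError("pedigree is not topologically ordered")

    @property
    def n(self) -> int:
        return len(self.animal_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal_id": self.animal_id, "sire_id": self.sire_id,
                             "dam_id": self.dam_id, "generation": self.generation})


@dataclass
class TraitArchitecture:
    """Parameters of the additive trait: general mean and variance components."""

    mu_true: float = 1.0
    sigma2_g: float = 1e-3
    sigma2_e: float = 3.0
    target_h2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variances must be >= 0")
        if self.target_h2 is not None and not (0.0 <= self.target_h2 <= 1.0):
            raise ValueError("target_h2 must lie in [0, 1]")


@dataclass
class SimulatedStudy:
    pedigree: Optional[PedigreeTable]
    genotypes: GenotypeMatrix
    phenotypes: np.ndarray
    true_marker_effects: np.ndarray
    residuals: np.ndarray
    arch: TraitArchitecture  # with sigma2_e as actually used
    seed: int


def simulate_pedigree(design: BreedingDesign, seed: int) -> PedigreeTable:
    """Generate the factorial-mating pedigree.

    The base generation consists of exactly n_sires males and n_dams females.
    In each later generation the required sires and dams are drawn uniformly
    at random, without replacement within each role, from the previous
    generation's males and females.  Offspring sex is a balanced 1:1 split in
    random order, so any design whose generations are at least twice the
    number of required parents of each sex is always feasible.
    """
    rng = np.random.default_rng(seed)
    ids, sires, dams, gens, sexes = [], [], [], [], []
    next_id = 1

    prev_ids = []
    prev_sex = []
    for _ in range(design.n_sires_per_gen):
        ids.append(next_id); sires.append(0); dams.append(0); gens.append(1)
        sexes.append("M"); prev_ids.append(next_id); prev_sex.append("M")
        next_id += 1
    for _ in range(design.n_dams_per_gen):
        ids.append(next_id); sires.append(0); dams.append(0); gens.append(1)
        sexes.append("F"); prev_ids.append(next_id); prev_sex.append("F")
        next_id += 1

    for gen in range(2, design.n_generations + 1):
        prev_ids_arr = np.asarray(prev_ids)
        prev_sex_arr = np.asarray(prev_sex)
        males = prev_ids_arr[prev_sex_arr == "M"]
        females = prev_ids_arr[prev_sex_arr == "F"]
        if len(males) < design.n_sires_per_gen:
            raise ValueError(
                f"generation {gen - 1} has {len(males)} males; "
                f"{design.n_sires_per_gen} sires required")
        if len(females) < design.n_dams_per_gen:
            raise ValueError(
                f"generation {gen - 1} has {len(females)} females; "
                f"{design.n_dams_per_gen} dams required")
        gen_sires = rng.choice(males, size=design.n_sires_per_gen, replace=False)
        gen_dams = rng.choice(females, size=design.n_dams_per_gen, replace=False)
        rng.shuffle(gen_dams)
        n_prog = design.progeny_per_gen
        prog_sex = np.array(["M", "F"] * (n_prog // 2) + ["M"] * (n_prog % 2))
        rng.shuffle(prog_sex)
        new_ids, new_sex = [], []
        k = 0
        for s_idx, sire in enumerate(gen_sires):
            mates = gen_dams[s_idx * design.dams_per_sire:(s_idx + 1) * design.dams_per_sire]
            for dam in mates:
                for _ in range(design.progeny_per_mating):
                    sex = prog_sex[k]; k += 1
                    ids.append(next_id); sires.append(int(sire)); dams.append(int(dam))
                    gens.append(gen); sexes.append(sex)
                    new_ids.append(next_id); new_sex.append(sex)
                    next_id += 1
        prev_ids, prev_sex = new_ids, new_sex

    return PedigreeTable(animal_id=np.asarray(ids), sire_id=np.asarray(sires),
                         dam_id=np.asarray(dams), generation=np.asarray(gens),
                         sex=np.asarray(sexes))


def marker_map(design: BreedingDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Marker ids, chromosome labels and positions (morgans, equally spaced)."""
    mc, L = design.markers_per_chromosome, design.chromosome_length
    within = np.linspace(0.0, L, mc) if mc > 1 else np.array([0.0])
    chrom = np.repeat(np.arange(1, design.n_chromosomes + 1), mc)
    pos = np.tile(within, design.n_chromosomes)
    ids = np.asarray([f"c{c}m{j + 1}" for c in range(1, design.n_chromosomes + 1)
                      for j in range(mc)])
    return ids, chrom, pos


def _gamete(hap: np.ndarray, chrom_slices, r: np.ndarray, rng) -> np.ndarray:
    """One recombinant gamete from a parent's (2, m) haplotype pair."""
    out = np.empty(hap.shape[1], dtype=np.int8)
    for sl in chrom_slices:
        m_c = sl.stop - sl.start
        start = rng.integers(0, 2)
        if m_c > 1:
            switches = rng.random(m_c - 1) < r[sl.start:sl.stop - 1]
            idx = np.empty(m_c, dtype=np.int64)
            idx[0] = start
            np.cumsum(switches, out=idx[1:])
            idx[1:] += start
            idx &= 1
        else:
            idx = np.array([start])
        out[sl] = hap[idx, np.arange(sl.start, sl.stop)]
    return out


def simulate_genotypes(pedigree: PedigreeTable, design: BreedingDesign,
                       seed: int,
                       founder_freq: Optional[np.ndarray] = None) -> GenotypeMatrix:
    """Gene-drop genotypes down the pedigree; returns the oriented 012 matrix.

    Founder allele frequencies are drawn uniform on the design's MAF band
    unless supplied explicitly.  The returned matrix counts the allele that
    is less frequent *in the realized data*, so downstream codings are
    well-defined regardless of drift.
    """
    rng = np.random.default_rng(seed)
    m = design.n_markers
    marker_ids, chrom, pos = marker_map(design)
    if founder_freq is None:
        founder_freq = rng.uniform(design.founder_maf_low, design.founder_maf_high, size=m)
    else:
        founder_freq = np.asarray(founder_freq, dtype=float)
        if founder_freq.shape != (m,):
            raise ValueError("founder_freq has wrong length for this design")

    mc = design.markers_per_chromosome
    chrom_slices = [slice(c * mc, (c + 1) * mc) for c in range(design.n_chromosomes)]
    # recombination fraction between adjacent markers (within chromosome)
    d = design.chromosome_length / (mc - 1) if mc > 1 else 0.0
    r = np.full(max(m - 1, 1), 0.5 * (1.0 - np.exp(-2.0 * d)))

    n = pedigree.n
    pos_of = {a: i for i, a in enumerate(pedigree.animal_id)}
    hap = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        sire, dam = pedigree.sire_id[i], pedigree.dam_id[i]
        if sire == 0 and dam == 0:
            hap[i, 0] = rng.random(m) < founder_freq
            hap[i, 1] = rng.random(m) < founder_freq
        else:
            hap[i, 0] = _gamete(hap[pos_of[sire]], chrom_slices, r, rng)
            hap[i, 1] = _gamete(hap[pos_of[dam]], chrom_slices, r, rng)

    raw = hap.sum(axis=1)
    return orient_to_minor(raw, animal_ids=pedigree.animal_id,
                           marker_ids=marker_ids, chrom=chrom, pos=pos)


def simulate_phenotypes(genotypes: GenotypeMatrix, arch: TraitArchitecture,
                        seed: int,
                        pedigree: Optional[PedigreeTable] = None) -> SimulatedStudy:
    """Draw marker effects and residuals and assemble y = 1*mu + Z0*g + e.

    When ``target_h2`` is set, sigma2_e is rescaled so that
    sigma2_a / (sigma2_a + sigma2_e) = target_h2 with
    sigma2_a = 2 * sum_j p_j (1 - p_j) * sigma2_g computed from the observed
    counted-allele frequencies.
    """
    rng = np.random.default_rng(seed)
    m = genotypes.m
    g_true = rng.normal(0.0, np.sqrt(arch.sigma2_g), size=m)
    sigma2_e = arch.sigma2_e
    if arch.target_h2 is not None:
        denom = genotypes.heterozygosity_sum()
        if denom <= 0.0:
            raise ValueError("target_h2 requires a polymorphic panel (genic variance > 0)")
        sigma2_a = denom * arch.sigma2_g
        if arch.target_h2 == 0.0:
            raise ValueError("target_h2 = 0 would require infinite residual variance")
        sigma2_e = sigma2_a * (1.0 - arch.target_h2) / arch.target_h2
    e = (np.zeros(genotypes.n) if sigma2_e == 0.0
         else rng.normal(0.0, np.sqrt(sigma2_e), size=genotypes.n))
    y = arch.mu_true + genotypes.Z0 @ g_true + e
    used = replace(arch, sigma2_e=sigma2_e)
    return SimulatedStudy(pedigree=pedigree, genotypes=genotypes, phenotypes=y,
                          true_marker_effects=g_true, residuals=e, arch=used,
                          seed=seed)


# ---------------------------------------------------------------------------
# Writers (tab-delimited, UTF-8, Unix newlines; unknown parent encoded as 0)


def write_pedigree_tsv(ped: PedigreeTable, path: str | Path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_phenotypes_tsv(study: SimulatedStudy, path: str | Path) -> None:
    pd.DataFrame({"animal_id": study.genotypes.animal_ids,
                  "y": study.phenotypes}).to_csv(path, sep="\t", index=False,
                                                 lineterminator="\n")


def write_true_effects_tsv(study: SimulatedStudy, path: str | Path) -> None:
    pd.DataFrame({"marker_id": study.genotypes.marker_ids,
                  "g_true": study.true_marker_effects}).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
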