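"""Allele coding of biallelic SNP design matrices.

A biallelic genotype can enter a linear model as 0/1/2 copies of either
allele, as -1/0/1, or with each marker column shifted by an arbitrary
constant.  All of these are members of one shift family

    Z = Z0 - 1_n v'

where ``Z0`` is the unique matrix counting copies of the *less frequent*
allele (the "012" coding) and ``v`` is a length-m shift vector.  The "210"
coding (counting the more frequent allele instead) is Z = 2·1 1' - Z0 and is
a sign flip rather than a shift.  This module builds ``Z0`` from raw counts,
applies the minor-allele-frequency filter, and produces coded design
matrices for the named schemes:

========  =============================================
name      definition
========  =============================================
012       v = 0 (the base coding)
101       v = 1, codes -1/0/1
centered  v = column means of Z0, columns sum to zero
210       2 - Z0 elementwise
custom    user-supplied v
========  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SCHEME_NAMES = ("012", "210", "101", "centered", "custom")

#: schemes of the form Z = Z0 - 1 v' (everything except the allele swap)
SHIFT_FAMILY = ("012", "101", "centered", "custom")


@dataclass
class GenotypeMatrix:
    """Animals x markers table of minor-allele counts.

    ``Z0`` is the unique base design: entry (i, j) counts how many copies of
    the less frequent allele at marker j animal i carries.  ``p`` holds the
    observed frequency of the counted allele, so p_j <= 0.5 except for exact
    ties kept in their original orientation.
    """

    Z0: np.ndarray
    animal_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # morgans
    p: np.ndarray
    flipped: np.ndarray = field(default=None)  # which columns were re-oriented

    def __post_init__(self) -> None:
        self.Z0 = np.asarray(self.Z0)
        if self.Z0.ndim != 2:
            raise ValueError("Z0 must be a 2-D matrix")
        if self.flipped is None:
            self.flipped = np.zeros(self.m, dtype=bool)

    @property
    def n(self) -> int:
        return self.Z0.shape[0]

    @property
    def m(self) -> int:
        return self.Z0.shape[1]

    def heterozygosity_sum(self) -> float:
        """2 * sum_j p_j (1 - p_j), the GBLUP variance scale denominator."""
        return float(2.0 * np.sum(self.p * (1.0 - self.p)))


@dataclass
class CodingScheme:
    """A named allele coding with its shift vector ``v`` (unused for 210)."""

    name: str
    v: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown coding scheme {self.name!r}")
        if self.v is not None:
            self.v = np.asarray(self.v, dtype=float)

    @classmethod
    def for_genotypes(cls, name: str, g: GenotypeMatrix,
                      v: Optional[np.ndarray] = None) -> "CodingScheme":
        """Build the scheme's shift vector for a concrete marker panel."""
        if name == "012":
            return cls(name, np.zeros(g.m))
        if name == "101":
            return cls(name, np.ones(g.m))
        if name == "centered":
            # column means of Z0; v/2 equals the observed allele frequencies
            return cls(name, g.Z0.mean(axis=0).astype(float))
        if name == "210":
            return cls(name, None)
        if name == "custom":
            if v is None:
                raise ValueError("custom scheme requires a shift vector v")
            v = np.asarray(v, dtype=float)
            if v.shape != (g.m,):
                raise ValueError(f"custom v has length {v.size}, expected {g.m}")
            return cls(name, v)
        raise ValueError(f"unknown coding scheme {name!r}")


@dataclass
class CodedDesign:
    """A real-valued design matrix Z under a named coding, tied to its source."""

    Z: np.ndarray
    scheme: CodingScheme
    source: GenotypeMatrix

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]


def orient_to_minor(raw_counts: np.ndarray,
                    animal_ids: Optional[Sequence] = None,
                    marker_ids: Optional[Sequence] = None,
                    chrom: Optional[np.ndarray] = None,
                    pos: Optional[np.ndarray] = None) -> GenotypeMatrix:
    """Flip columns so the counted allele is the less frequent one.

    Columns whose counted-allele frequency exceeds 0.5 are replaced by
    ``2 - x``.  Exact ties at 0.5 keep their original orientation (recorded
    in ``flipped`` so a run is reproducible).  Idempotent.
    """
    X = np.asarray(raw_counts)
    if X.ndim != 2:
        raise ValueError("raw_counts must be 2-D (animals x markers)")
    if not np.isin(X, (0, 1, 2)).all():
        raise ValueError("genotype entries must be allele counts in {0, 1, 2}")
    X = X.astype(np.int8)
    n, m = X.shape
    freq = X.mean(axis=0) / 2.0
    flip = freq > 0.5
    Z0 = X.copy()
    Z0[:, flip] = 2 - Z0[:, flip]
    p = Z0.mean(axis=0) / 2.0
    if animal_ids is None:
        animal_ids = np.arange(1, n + 1)
    if marker_ids is None:
        marker_ids = np.array([f"m{j + 1}" for j in range(m)])
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    if pos is None:
        pos = np.zeros(m)
    return GenotypeMatrix(Z0=Z0, animal_ids=np.asarray(animal_ids),
                          marker_ids=np.asarray(marker_ids),
                          chrom=np.asarray(chrom), pos=np.asarray(pos),
                          p=p, flipped=flip)


def maf_filter(g: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Drop markers with minor allele frequency strictly below ``threshold``.

    The comparison is strict ("less than"), so a marker at exactly the
    threshold frequency survives.  Marker order is preserved.
    """
    if not (0.0 <= threshold <= 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    keep = g.p >= threshold
    return GenotypeMatrix(Z0=g.Z0[:, keep], animal_ids=g.animal_ids,
                          marker_ids=g.marker_ids[keep], chrom=g.chrom[keep],
                          pos=g.pos[keep], p=g.p[keep], flipped=g.flipped[keep])


def apply_coding(g: GenotypeMatrix, scheme: CodingScheme | str,
                 v: Optional[np.ndarray] = None) -> CodedDesign:
    """Produce the coded design matrix Z for ``scheme``.

    Shift-family schemes use Z = Z0 - 1_n v'; the 210 scheme uses Z = 2 - Z0.
    The transformation preserves the spacing between the three possible codes
    within every marker.
    """
    if isinstance(scheme, str):
        scheme = CodingScheme.for_genotypes(scheme, g, v=v)
    Z0 = g.Z0.astype(float)
    if scheme.name == "210":
        Z = 2.0 - Z0
    else:
        if scheme.v is None or scheme.v.shape != (g.m,):
            raise ValueError("shift vector v has wrong length for this panel")
        Z = Z0 - scheme.v[np.newaxis, :]
    return CodedDesign(Z=Z, scheme=scheme, source=g)


# ---------------------------------------------------------------------------
# I/O


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV (first column animal_id, one column per marker)."""
    df = pd.read_csv(path, sep="\t")
    animal_ids = df.iloc[:, 0].to_numpy()
    marker_ids = df.columns[1:].to_numpy()
    raw = df.iloc[:, 1:].to_numpy()
    return orient_to_minor(raw, animal_ids=animal_ids, marker_ids=marker_ids)


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.Z0, columns=g.marker_ids)
    df.insert(0, "animal_id", g.animal_ids)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Import 0/1/2 dosages from the GT field of a VCF.

    Maps 0/0 -> 0, 0/1 -> 1, 1/1 -> 2 and then orients every column to count
    the minor allele.  Missing genotypes and non-biallelic records are
    rejected: the analyses here assume complete biallelic data.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    cols, ids, chroms, poss = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=missing, 3=hom alt
        if (gt == 2).any():
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        dose = np.where(gt == 3, 2, gt)
        cols.append(dose)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not cols:
        raise ValueError("VCF contains no variant records")
    raw = np.column_stack(cols)
    return orient_to_minor(raw, animal_ids=samples, marker_ids=np.asarray(ids),
                           chrom=np.asarray(chroms), pos=np.asarray(poss, dtype=float))
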