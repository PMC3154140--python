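"""Henderson mixed-model equations for the marker model and its GBLUP equivalent.

Marker model (SNP-BLUP):  y = 1*mu + Z g + e,  g ~ N(0, I sigma2_g),
e ~ N(0, I sigma2_e).  The coefficient system solved here is

    [ n/se2      1'Z/se2          ] [mu]   [1'y/se2]
    [ Z'1/se2    Z'Z/se2 + I/sg2  ] [g ] = [Z'y/se2]

whose full inverse gives Var(mu|y), Cov(mu, g|y) and C_g = Var(g|y).

Equivalent model (GBLUP): a = Z g with prior a ~ N(0, G sigma2_a),
G = Z Z' / (2 sum_j p_j (1 - p_j)).  Its MME are

    [ n/se2   1'/se2            ] [mu]   [1'y/se2]
    [ 1/se2   I/se2 + Ginv/sa2  ] [a ] = [ y/se2 ]

Prediction error variances are the breeding-value diagonal of the inverse
coefficient matrix, and reliability_i = 1 - PEV_i / (G_ii * sigma2_a).

Inference on (mu-free) quantities is identical across allele codings; PEV and
reliabilities are not, because Z itself differs by coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import linalg

from .coding import CodedDesign, CodingScheme, GenotypeMatrix


@dataclass
class VarianceComponents:
    """(sigma2_g, sigma2_e) with the GBLUP scale sigma2_a = 2*sum p(1-p) * sigma2_g."""

    sigma2_g: float
    sigma2_e: float
    scale_denominator: float = 1.0  # 2 * sum_j p_j (1 - p_j)

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0 or self.scale_denominator < 0:
            raise ValueError("variance components must be >= 0")

    @property
    def sigma2_a(self) -> float:
        return self.scale_denominator * self.sigma2_g

    @classmethod
    def from_marker(cls, sigma2_g: float, sigma2_e: float,
                    g: GenotypeMatrix) -> "VarianceComponents":
        return cls(sigma2_g, sigma2_e, g.heterozygosity_sum())

    @classmethod
    def from_additive(cls, sigma2_a: float, sigma2_e: float,
                      g: GenotypeMatrix) -> "VarianceComponents":
        denom = g.heterozygosity_sum()
        if denom <= 0:
            raise ValueError("panel has zero genic variance")
        return cls(sigma2_a / denom, sigma2_e, denom)

    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else np.nan


@dataclass
class GenomicRelationship:
    G: np.ndarray
    scheme: CodingScheme
    diagonal_inflation: float = 1.0

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def raw_diagonal(self) -> np.ndarray:
        """Diagonal before inflation — used in the reliability denominator."""
        return np.diag(self.G) / self.diagonal_inflation


@dataclass
class MarkerFit:
    mu_hat: float
    g_hat: np.ndarray
    c_mumu: float
    c_mug: np.ndarray
    C_g: np.ndarray
    scheme: CodingScheme
    vc: VarianceComponents


@dataclass
class GblupFit:
    mu_hat: float
    a_hat: np.ndarray
    pev: np.ndarray
    reliability: np.ndarray
    complete_values: np.ndarray
    scheme: CodingScheme
    vc: VarianceComponents


def build_grm(design: CodedDesign, vc: Optional[VarianceComponents] = None,
              inflation: float = 1.0) -> GenomicRelationship:
    """G = Z Z' / (2 sum p(1-p)); optionally inflate the diagonal.

    The centered coding yields a singular G (its Z has zero column sums, so
    G 1 = 0); multiplying the diagonal by e.g. 1.001 restores invertibility.
    """
    denom = design.source.heterozygosity_sum()
    if denom <= 0:
        raise ValueError("cannot scale G: panel has zero genic variance")
    G = design.Z @ design.Z.T / denom
    if inflation != 1.0:
        G = G.copy()
        np.fill_diagonal(G, np.diag(G) * inflation)
    return GenomicRelationship(G=G, scheme=design.scheme, diagonal_inflation=inflation)


def _marker_coefficient_matrix(design: CodedDesign,
                               vc: VarianceComponents) -> tuple[np.ndarray, np.ndarray]:
    Z = design.Z
    n, m = Z.shape
    se2, sg2 = vc.sigma2_e, vc.sigma2_g
    Q = np.empty((1 + m, 1 + m))
    Q[0, 0] = n / se2
    z1 = Z.sum(axis=0)
    Q[0, 1:] = z1 / se2
    Q[1:, 0] = z1 / se2
    Q[1:, 1:] = Z.T @ Z / se2
    Q[1:, 1:].flat[:: m + 1] += 1.0 / sg2
    return Q, Z


def solve_marker_mme(y: np.ndarray, design: CodedDesign,
                     vc: VarianceComponents) -> MarkerFit:
    """Solve the SNP-BLUP MME and return solutions plus inverse blocks."""
    y = np.asarray(y, dtype=float)
    n, m = design.Z.shape
    if n < 2:
        raise ValueError("need at least two records")
    if y.shape != (n,):
        raise ValueError("phenotype vector does not match the design")
    if vc.sigma2_g <= 0 or vc.sigma2_e <= 0:
        raise ValueError("variance components must be positive")
    Q, Z = _marker_coefficient_matrix(design, vc)
    rhs = np.empty(1 + m)
    rhs[0] = y.sum() / vc.sigma2_e
    rhs[1:] = Z.T @ y / vc.sigma2_e
    try:
        cho = linalg.cho_factor(Q, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - cannot occur for sg2 > 0
        raise linalg.LinAlgError("singular marker MME coefficient matrix") from exc
    C = linalg.cho_solve(cho, np.eye(1 + m))
    sol = C @ rhs
    return MarkerFit(mu_hat=float(sol[0]), g_hat=sol[1:], c_mumu=float(C[0, 0]),
                     c_mug=C[0, 1:].copy(), C_g=C[1:, 1:], scheme=design.scheme,
                     vc=vc)


def complete_gebv(fit: MarkerFit, design: CodedDesign) -> np.ndarray:
    """Complete genomic breeding values a_d = 1*mu_hat + Z g_hat (coding-invariant)."""
    if fit.scheme is not design.scheme and fit.scheme.name != design.scheme.name:
        raise ValueError("fit and design come from different coding schemes")
    return fit.mu_hat + design.Z @ fit.g_hat


def pev_marker(fit: MarkerFit, design: CodedDesign) -> np.ndarray:
    """PEV_i = [Z C_g Z']_ii — depends on the coding through Z, not through C_g."""
    ZC = design.Z @ fit.C_g
    return np.einsum("ij,ij->i", ZC, design.Z)


def var_complete(fit: MarkerFit, design: CodedDesign) -> np.ndarray:
    """Var(a_d | y) = 1 c_mumu 1' + 1 c_mug' Z' + Z c_mug 1' + Z C_g Z'.

    Independent of the allele coding; under centered coding the cross term
    vanishes and the matrix equals (sigma2_e/n) J + Z_c C_g Z_c'.
    """
    Z = design.Z
    cross = Z @ fit.c_mug
    return (fit.c_mumu + cross[np.newaxis, :] + cross[:, np.newaxis]
            + Z @ fit.C_g @ Z.T)


def solve_gblup_mme(y: np.ndarray, G: GenomicRelationship, vc: VarianceComponents,
                    use_inflated_diagonal: bool = False) -> GblupFit:
    """Solve the equivalent-model MME; PEV and reliabilities from its inverse."""
    y = np.asarray(y, dtype=float)
    n = G.n
    if y.shape != (n,):
        raise ValueError("phenotype vector does not match G")
    if vc.sigma2_a <= 0 or vc.sigma2_e <= 0:
        raise ValueError("variance components must be positive")
    try:
        Ginv = linalg.inv(G.G)
        # symmetrize against round-off; reject badly conditioned G explicitly
        if not np.isfinite(Ginv).all():
            raise linalg.LinAlgError
        cond = np.linalg.cond(G.G)
        if cond > 1e12:
            raise linalg.LinAlgError
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "G is singular (centered coding or duplicate genotypes); "
            "regularize first, e.g. build_grm(..., inflation=1.001)") from exc
    se2, sa2 = vc.sigma2_e, vc.sigma2_a
    Q = np.empty((1 + n, 1 + n))
    Q[0, 0] = n / se2
    Q[0, 1:] = 1.0 / se2
    Q[1:, 0] = 1.0 / se2
    Q[1:, 1:] = Ginv / sa2
    Q[1:, 1:].flat[:: n + 1] += 1.0 / se2
    rhs = np.empty(1 + n)
    rhs[0] = y.sum() / se2
    rhs[1:] = y / se2
    C = linalg.inv(Q)
    sol = C @ rhs
    mu_hat = float(sol[0])
    a_hat = sol[1:]
    pev = np.diag(C)[1:].copy()
    gdiag = np.diag(G.G) if use_inflated_diagonal else G.raw_diagonal
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 1.0 - pev / (gdiag * sa2)
    return GblupFit(mu_hat=mu_hat, a_hat=a_hat, pev=pev, reliability=rel,
                    complete_values=mu_hat + a_hat, scheme=G.scheme, vc=vc)


def reliability_report(fits: Dict[str, GblupFit]) -> dict:
    """Per-scheme reliability summaries and their pairwise correlations.

    Schemes whose reliability vector is constant carry no correlation
    information; they are listed under ``degenerate`` and excluded from the
    correlation matrix rather than propagating NaN.
    """
    if not fits:
        raise ValueError("no fits supplied")
    n_ref = next(iter(fits.values())).a_hat.size
    for f in fits.values():
        if f.a_hat.size != n_ref:
            raise ValueError("fits cover different animal sets")
    rows = {name: {"min": float(np.min(f.reliability)),
                   "mean": float(np.mean(f.reliability)),
                   "max": float(np.max(f.reliability)),
                   "sd": float(np.std(f.reliability, ddof=1))}
            for name, f in fits.items()}
    summary = pd.DataFrame(rows).T
    degenerate = [name for name, f in fits.items()
                  if np.ptp(f.reliability) == 0.0]
    usable = [name for name in fits if name not in degenerate]
    if usable:
        mat = np.corrcoef(np.vstack([fits[name].reliability for name in usable]))
        mat = np.atleast_2d(mat)
        corr = pd.DataFrame(mat, index=usable, columns=usable)
    else:
        corr = pd.DataFrame(index=[], columns=[])
    return {"summary": summary, "correlations": corr, "degenerate": degenerate}


def write_gblup_tsv(fit: GblupFit, animal_ids: np.ndarray, path) -> None:
    pd.DataFrame({"animal_id": animal_ids, "a_hat": fit.a_hat,
                  "complete_value": fit.complete_values, "pev": fit.pev,
                  "reliability": fit.reliability}).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def write_marker_tsv(fit: MarkerFit, marker_ids: np.ndarray, path) -> None:
    pd.DataFrame({"marker_id": marker_ids, "g_hat": fit.g_hat}).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
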