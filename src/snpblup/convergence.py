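"""Theoretical convergence rates of Gibbs samplers for [mu, g | y].

For a multivariate normal target with precision matrix Q partitioned into s
ordered blocks, the Gibbs sampler that sweeps the blocks in order converges
geometrically at rate rho = the largest-modulus eigenvalue of

    B = (I - L)^-1 U,

where A_ij = -(Q_ii)^-1 Q_ij for i != j (A_ii = 0), L is the block lower
triangle of A and U = A - L.  The same rho also measures the lag-1
autocorrelation of the stationary chain, i.e. mixing.

For the marker model the precision of [mu, g | y] at fixed variances is

    Q = [ n/se2      1'Z/se2          ]
        [ Z'1/se2    Z'Z/se2 + I/sg2  ]

Two standard blockings: the two-block scheme {mu}, {g} (rate rho1) and the
fully single-site scheme (rate rho2, the stochastic Gauss-Seidel).  Under
centered allele coding the cross block Z'1 vanishes, so rho1 = 0 — the
two-block sampler becomes exact Monte Carlo.

The relative mixing of coding X against a reference is
k = log(rho_ref)/log(rho_X): the factor by which chain length must grow to
match the reference's mixing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .coding import CodedDesign
from .mme import VarianceComponents


@dataclass
class JointPrecision:
    """Precision matrix of [mu, g | y]; index 0 is mu, then the m markers."""

    Q: np.ndarray
    n: int
    scheme: str

    @property
    def m(self) -> int:
        return self.Q.shape[0] - 1


@dataclass
class ConvergenceReport:
    rates: pd.DataFrame          # per scheme: rho1 (block), rho2 (single-site)
    relative: pd.DataFrame       # per scheme: k vs the reference
    reference: str


def build_joint_precision(design: CodedDesign, vc: VarianceComponents) -> JointPrecision:
    Z = design.Z
    n, m = Z.shape
    if vc.sigma2_g <= 0 or vc.sigma2_e <= 0:
        raise ValueError("variances must be positive")
    Q = np.empty((1 + m, 1 + m))
    Q[0, 0] = n / vc.sigma2_e
    z1 = Z.sum(axis=0)
    Q[0, 1:] = z1 / vc.sigma2_e
    Q[1:, 0] = z1 / vc.sigma2_e
    Q[1:, 1:] = Z.T @ Z / vc.sigma2_e
    Q[1:, 1:].flat[:: m + 1] += 1.0 / vc.sigma2_g
    return JointPrecision(Q=Q, n=n, scheme=design.scheme.name)


def gibbs_rate(Q: JointPrecision | np.ndarray,
               blocking: Sequence[Sequence[int]]) -> float:
    """Spectral radius of B = (I - L)^-1 U for the given ordered blocking.

    ``blocking`` must partition {0, ..., dim-1}.  Eigenvalues of B may be
    complex; the rate is the maximum modulus.
    """
    Qm = Q.Q if isinstance(Q, JointPrecision) else np.asarray(Q, dtype=float)
    dim = Qm.shape[0]
    blocks = [np.asarray(b, dtype=int) for b in blocking]
    flat = np.concatenate(blocks) if blocks else np.array([], dtype=int)
    if sorted(flat.tolist()) != list(range(dim)):
        raise ValueError("blocking must partition all indices exactly once")

    # block order of each variable, for the L/U split
    order = np.empty(dim, dtype=int)
    for k, b in enumerate(blocks):
        order[b] = k

    # A = -blockdiag(Q_ii)^-1 Q with zeroed diagonal blocks
    A = np.empty_like(Qm)
    for b in blocks:
        sub = Qm[np.ix_(b, b)]
        try:
            A[b, :] = -linalg.solve(sub, Qm[b, :], assume_a="sym")
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(f"singular diagonal block {b}") from exc
        A[np.ix_(b, b)] = 0.0

    lower = order[:, np.newaxis] > order[np.newaxis, :]
    L = np.where(lower, A, 0.0)
    U = A - L
    B = linalg.solve(np.eye(dim) - L, U)
    eigs = np.linalg.eigvals(B)
    return float(np.max(np.abs(eigs)))


def rate_two_block(Q: JointPrecision) -> float:
    """rho1: the {mu}, {g} two-block scheme."""
    dim = Q.Q.shape[0]
    return gibbs_rate(Q, [[0], list(range(1, dim))])


def rate_single_site(Q: JointPrecision) -> float:
    """rho2: mu, g_1, ..., g_m updated one at a time (stochastic Gauss-Seidel)."""
    dim = Q.Q.shape[0]
    return gibbs_rate(Q, [[i] for i in range(dim)])


def relative_mixing(rho_ref: float, rho: float) -> float:
    """k = log(rho_ref)/log(rho): chain-length factor needed to match the reference.

    rho = 0 mixes instantly, reported as k = 0; rho = 1 (no geometric
    convergence) has no defined k.
    """
    if not (0.0 < rho_ref < 1.0):
        raise ValueError("reference rate must lie strictly in (0, 1)")
    if rho == 0.0:
        return 0.0
    if not (0.0 < rho < 1.0):
        raise ValueError("rate must lie in [0, 1); k is undefined at rho = 1")
    return float(np.log(rho_ref) / np.log(rho))


def _snap(rho: float, tol: float = 1e-12) -> float:
    return 0.0 if rho < tol else rho


def convergence_report(designs: Dict[str, CodedDesign], vc: VarianceComponents,
                       reference: str = "012") -> ConvergenceReport:
    """Table of rho1/rho2 per coding plus relative mixing against a reference."""
    if reference not in designs:
        raise ValueError(f"reference scheme {reference!r} not among the designs")
    rows = {}
    for name, design in designs.items():
        Q = build_joint_precision(design, vc)
        # snap numerically-zero rates (centered rho1) to an exact zero
        rows[name] = {"rho1_block": _snap(rate_two_block(Q)),
                      "rho2_single_site": _snap(rate_single_site(Q))}
    rates = pd.DataFrame(rows).T
    rel = {}
    for name in designs:
        rel[name] = {}
        for col, key in (("rho1_block", "k_block"), ("rho2_single_site", "k_single_site")):
            rho_ref, rho = rates.loc[reference, col], rates.loc[name, col]
            try:
                rel[name][key] = relative_mixing(rho_ref, rho)
            except ValueError:
                rel[name][key] = np.nan
    return ConvergenceReport(rates=rates, relative=pd.DataFrame(rel).T,
                             reference=reference)
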