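"""REML variance-component estimation for the marker and GBLUP models.

Both models have marginal covariance V = sigma2 * K + sigma2_e * I with a
single fixed intercept: K = Z Z' for the marker model (sigma2 = per-marker
variance sigma2_g) and K = G for the equivalent model (sigma2 = additive
variance sigma2_a).  The restricted log-likelihood is evaluated in the
error-contrast form

    lR = -1/2 [ (n-1) log 2*pi + log|V| + log(1'V^-1 1) - log n + y'Py ],

with P = V^-1 - V^-1 1 (1'V^-1 1)^-1 1'V^-1, which matches the density of
K y for any orthonormal contrast basis K with K 1 = 0.  Because the
intercept is profiled out, the value — and hence the REML estimates — are
identical under every allele coding of the marker model.

Two optimizers are provided:

* ``em_reml`` — the classical EM recursion driven by the MME inverse
  (monotone in lR, slow near the optimum);
* ``ai_reml`` — average-information (quasi-Newton) updates with an EM
  fallback whenever an AI step would leave the parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy import linalg

from .coding import CodedDesign
from .mme import GenomicRelationship, VarianceComponents, solve_marker_mme

ModelInput = Union[CodedDesign, GenomicRelationship, np.ndarray]


@dataclass
class RemlResult:
    estimates: VarianceComponents
    algorithm: str  # "EM" | "AI"
    model: str      # "marker" | "gblup"
    scheme: Optional[str]
    n_iterations: int
    converged: bool
    final_criterion: float
    loglik_path: List[float] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1] if self.loglik_path else np.nan


def _unpack(design_or_G: ModelInput):
    """Return (model, K, scheme, scale_denominator) for either model form."""
    if isinstance(design_or_G, CodedDesign):
        K = design_or_G.Z @ design_or_G.Z.T
        return "marker", K, design_or_G.scheme.name, design_or_G.source.heterozygosity_sum()
    if isinstance(design_or_G, GenomicRelationship):
        return "gblup", design_or_G.G, design_or_G.scheme.name, 1.0
    K = np.asarray(design_or_G, dtype=float)
    return "gblup", K, None, 1.0


def _loglik_K(sigma2: float, sigma2_e: float, K: np.ndarray, y: np.ndarray) -> float:
    n = y.size
    V = sigma2 * K + sigma2_e * np.eye(n)
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError("V is not positive definite") from exc
    logdet_V = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ones = np.ones(n)
    Vi_y = linalg.cho_solve(cho, y)
    Vi_1 = linalg.cho_solve(cho, ones)
    xvx = ones @ Vi_1
    yPy = y @ Vi_y - (ones @ Vi_y) ** 2 / xvx
    return float(-0.5 * ((n - 1) * np.log(2.0 * np.pi) + logdet_V
                         + np.log(xvx) - np.log(n) + yPy))


def reml_loglik(vc: VarianceComponents, y: np.ndarray,
                design_or_G: ModelInput) -> float:
    """Restricted log-likelihood of y at the given variance components.

    For a ``CodedDesign`` the genetic scale is ``vc.sigma2_g`` (V = ZZ' sg2 +
    I se2); for a relationship matrix it is ``vc.sigma2_a`` (V = G sa2 +
    I se2).  The additive constants are fixed so the two forms agree whenever
    ZZ' sg2 = G sa2.
    """
    y = np.asarray(y, dtype=float)
    model, K, _, _ = _unpack(design_or_G)
    sigma2 = vc.sigma2_g if model == "marker" else vc.sigma2_a
    if sigma2 < 0 or vc.sigma2_e <= 0:
        raise ValueError("variances must be positive (sigma2_e strictly)")
    return _loglik_K(sigma2, vc.sigma2_e, K, y)


def _result_vc(model: str, sigma2: float, sigma2_e: float,
               denom: float) -> VarianceComponents:
    if model == "marker":
        return VarianceComponents(sigma2, sigma2_e, denom)
    # gblup: sigma2 is already on the additive scale
    return VarianceComponents(sigma2, sigma2_e, 1.0)


def _em_step_marker(y: np.ndarray, design: CodedDesign, sg2: float,
                    se2: float) -> tuple[float, float]:
    n, m = design.Z.shape
    fit = solve_marker_mme(y, design, VarianceComponents(sg2, se2))
    sg2_new = float(fit.g_hat @ fit.g_hat + np.trace(fit.C_g)) / m
    resid = y - fit.mu_hat - design.Z @ fit.g_hat
    se2_new = float(y @ resid) / (n - 1)
    return sg2_new, se2_new


def _em_step_gblup(y: np.ndarray, G: np.ndarray, Ginv: np.ndarray, sa2: float,
                   se2: float) -> tuple[float, float]:
    n = y.size
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
    mu_hat, a_hat = float(sol[0]), sol[1:]
    Ca = C[1:, 1:]
    sa2_new = float(a_hat @ Ginv @ a_hat + np.sum(Ginv * Ca)) / n
    se2_new = float(y @ (y - mu_hat - a_hat)) / (n - 1)
    return sa2_new, se2_new


def em_reml(y: np.ndarray, design_or_G: ModelInput, start: VarianceComponents,
            tol: float = 1e-8, max_iter: int = 500) -> RemlResult:
    """EM-REML.  Monotone in the restricted log-likelihood; slow near the top."""
    y = np.asarray(y, dtype=float)
    model, K, scheme, denom = _unpack(design_or_G)
    sigma2 = start.sigma2_g if model == "marker" else start.sigma2_a
    se2 = start.sigma2_e
    if sigma2 <= 0 or se2 <= 0:
        raise ValueError("starting variances must be positive")
    Ginv = linalg.inv(K) if model == "gblup" else None
    path = [_loglik_K(sigma2, se2, K, y)]
    crit = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if model == "marker":
            new_sigma2, new_se2 = _em_step_marker(y, design_or_G, sigma2, se2)
        else:
            new_sigma2, new_se2 = _em_step_gblup(y, K, Ginv, sigma2, se2)
        crit = max(abs(new_sigma2 - sigma2) / max(abs(sigma2), 1e-300),
                   abs(new_se2 - se2) / max(abs(se2), 1e-300))
        sigma2, se2 = new_sigma2, new_se2
        path.append(_loglik_K(sigma2, se2, K, y))
        if crit < tol:
            converged = True
            break
    return RemlResult(estimates=_result_vc(model, sigma2, se2, denom),
                      algorithm="EM", model=model, scheme=scheme,
                      n_iterations=it, converged=converged,
                      final_criterion=float(crit), loglik_path=path)


def _score_and_ai(sigma2: float, se2: float, K: np.ndarray, y: np.ndarray):
    """REML score vector and average-information matrix for (sigma2, sigma2_e)."""
    n = y.size
    V = sigma2 * K + se2 * np.eye(n)
    cho = linalg.cho_factor(V, lower=True)
    Vi = linalg.cho_solve(cho, np.eye(n))
    ones = np.ones(n)
    Vi1 = Vi @ ones
    P = Vi - np.outer(Vi1, Vi1) / (ones @ Vi1)
    Py = P @ y
    KPy = K @ Py
    PKPy = P @ KPy
    PPy = P @ Py
    score = np.array([
        -0.5 * (np.sum(P * K) - Py @ KPy),
        -0.5 * (np.trace(P) - Py @ Py),
    ])
    ai = 0.5 * np.array([
        [KPy @ PKPy, KPy @ PPy],
        [KPy @ PPy, Py @ PPy],
    ])
    return score, ai, Py, P


def ai_reml(y: np.ndarray, design_or_G: ModelInput, start: VarianceComponents,
            tol: float = 1e-8, max_iter: int = 50) -> RemlResult:
    """Average-information REML with EM fallback steps.

    Whenever a Newton/AI step proposes a non-positive variance, the iteration
    falls back to the (always-interior) EM update for that round.
    """
    y = np.asarray(y, dtype=float)
    model, K, scheme, denom = _unpack(design_or_G)
    sigma2 = start.sigma2_g if model == "marker" else start.sigma2_a
    se2 = start.sigma2_e
    if sigma2 <= 0 or se2 <= 0:
        raise ValueError("starting variances must be positive")
    n = y.size
    path = [_loglik_K(sigma2, se2, K, y)]
    crit = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, ai, Py, P = _score_and_ai(sigma2, se2, K, y)
        try:
            delta = linalg.solve(ai, score, assume_a="sym")
        except linalg.LinAlgError:
            delta = np.full(2, np.nan)
        cand = np.array([sigma2, se2]) + delta
        if not np.isfinite(cand).all() or (cand <= 0).any():
            # EM fallback expressed through P:  s2 <- s2 + s2^2 (y'PKPy - tr(PK))/q
            tr_PK = np.sum(P * K)
            yPKPy = Py @ (K @ Py)
            # number of effect levels: m for the marker model, n for gblup
            q_g = design_or_G.Z.shape[1] if model == "marker" else K.shape[0]
            cand = np.array([
                sigma2 + sigma2 ** 2 * (yPKPy - tr_PK) / q_g,
                se2 + se2 ** 2 * ((Py @ Py) - np.trace(P)) / (n - 1),
            ])
            cand = np.maximum(cand, np.array([sigma2, se2]) * 1e-6)
        crit = max(abs(cand[0] - sigma2) / max(abs(sigma2), 1e-300),
                   abs(cand[1] - se2) / max(abs(se2), 1e-300))
        sigma2, se2 = float(cand[0]), float(cand[1])
        path.append(_loglik_K(sigma2, se2, K, y))
        if crit < tol:
            converged = True
            break
    return RemlResult(estimates=_result_vc(model, sigma2, se2, denom),
                      algorithm="AI", model=model, scheme=scheme,
                      n_iterations=it, converged=converged,
                      final_criterion=float(crit), loglik_path=path)
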