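"""Gaussian-copula joint distribution for two binary outcomes.

Marginal efficacy/toxicity probabilities ``pE, pT`` are linked into a joint
(2x2) distribution through a Gaussian copula with correlation ``alpha``::

    p00 = Phi2( Phi^{-1}(1 - pE), Phi^{-1}(1 - pT) | alpha )

and the remaining cells follow by complement algebra:
``p10 = (1 - pT) - p00``, ``p01 = (1 - pE) - p00``,
``p11 = pE + pT - 1 + p00``.  Independence (``alpha = 0``) reduces p00 to
the product of the complements.

The bivariate normal CDF is evaluated with Owen's T function, which is
vectorized and accurate to ~1e-14 — essential because the simulation study
evaluates it over dose grid x patient x replicate.

The copula correlation is estimated by two-stage pseudo-likelihood: the
marginal models are fitted first, their per-subject probabilities are
plugged into the copula cell likelihood, and ``alpha`` maximizes the summed
log-likelihood over (-0.99, 0.99).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri, owens_t

logger = logging.getLogger(__name__)

__all__ = [
    "CopulaSpec",
    "bvn_cdf",
    "joint_from_marginals",
    "frechet_bounds",
    "copula_loglik",
    "estimate_alpha",
]

ALPHA_CAP = 0.99  # numerical cap on |alpha|
_PROB_CLIP = 1e-10  # marginal probabilities clipped away from {0, 1}


@dataclass(frozen=True)
class CopulaSpec:
    """Copula correlation and mode; independence mode ignores ``alpha``."""

    alpha: float = 0.0
    mode: Literal["copula", "independence"] = "copula"

    def __post_init__(self) -> None:
        if self.mode == "copula" and abs(self.alpha) > ALPHA_CAP:
            raise ValueError(f"|alpha| must be <= {ALPHA_CAP}")


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF ``P(X <= h, Y <= k)`` with correlation
    ``rho``, via Owen's T:

        Phi2(h,k,rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - beta

    with ``a_h = (k - rho h)/(h sqrt(1-rho^2))`` (and symmetrically a_k),
    ``beta = 1/2`` when h and k have opposite signs, else 0.  Exact zeros in
    h or k are nudged by 1e-13 to keep the a-ratios finite (error far below
    the package's 1e-9 joint tolerance).
    """
    if abs(rho) >= 1.0:
        # degenerate comonotone / countermonotone limits
        h, k = np.broadcast_arrays(np.asarray(h, float), np.asarray(k, float))
        if rho >= 1.0:
            return ndtr(np.minimum(h, k))
        return np.clip(ndtr(h) + ndtr(k) - 1.0, 0.0, None)
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    eps = 1e-13
    h = np.where(h == 0.0, eps, h)
    k = np.where(k == 0.0, eps, k)
    s = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * s)
    a_k = (h - rho * k) / (k * s)
    beta = np.where(h * k < 0.0, 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    return np.clip(out, 0.0, 1.0)


def frechet_bounds(p_e: np.ndarray, p_t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Feasible range ``[max(0, pE+pT-1), min(pE, pT)]`` for p11 given the
    two marginals."""
    p_e = np.asarray(p_e, dtype=float)
    p_t = np.asarray(p_t, dtype=float)
    upper = np.minimum(p_e, p_t)
    # guard against floating error making lower exceed upper (e.g. pE=1)
    lower = np.minimum(np.maximum(0.0, p_e + p_t - 1.0), upper)
    return lower, upper


def joint_from_marginals(
    p_e: np.ndarray, p_t: np.ndarray, spec: CopulaSpec | float
) -> np.ndarray:
    """Joint cell probabilities (..., 4) in order (p00, p10, p01, p11) from
    the marginals under the Gaussian copula (or independence).

    Marginals are clipped into ``[1e-10, 1 - 1e-10]`` before the probit
    transform; the output reproduces the (clipped) marginals to 1e-9 and
    always satisfies the Frechet bounds.
    """
    if not isinstance(spec, CopulaSpec):
        spec = CopulaSpec(alpha=float(spec), mode="copula")
    p_e = np.clip(np.asarray(p_e, dtype=float), _PROB_CLIP, 1.0 - _PROB_CLIP)
    p_t = np.clip(np.asarray(p_t, dtype=float), _PROB_CLIP, 1.0 - _PROB_CLIP)
    p_e, p_t = np.broadcast_arrays(p_e, p_t)
    q_e = 1.0 - p_e  # Pr(E=0)
    q_t = 1.0 - p_t  # Pr(T=0)
    if spec.mode == "independence":
        p00 = q_e * q_t
    else:
        p00 = bvn_cdf(ndtri(q_e), ndtri(q_t), spec.alpha)
        # copula value is bracketed by the Frechet bounds for p00
        p00 = np.clip(p00, np.maximum(0.0, q_e + q_t - 1.0), np.minimum(q_e, q_t))
    p10 = q_t - p00
    p01 = q_e - p00
    p11 = p_e + p_t - 1.0 + p00
    joint = np.stack([p00, p10, p01, p11], axis=-1)
    return np.clip(joint, 0.0, 1.0)


def copula_loglik(
    e: np.ndarray,
    t: np.ndarray,
    p_e: np.ndarray,
    p_t: np.ndarray,
    alpha: float,
    mode: Literal["copula", "independence"] = "copula",
) -> float:
    """Pseudo-log-likelihood of binary outcomes (e, t) given per-subject
    marginal probabilities, summed over subjects.

    Cell probabilities are floored at 1e-12 before the log.
    """
    e = np.asarray(e, dtype=int)
    t = np.asarray(t, dtype=int)
    joint = joint_from_marginals(p_e, p_t, CopulaSpec(alpha=alpha, mode=mode))
    cells = joint[np.arange(e.size), e + 2 * t]
    n_floored = int(np.sum(cells < 1e-12))
    if n_floored:
        logger.debug("floored %d zero cell probabilities in copula loglik", n_floored)
    return float(np.sum(np.log(np.maximum(cells, 1e-12))))


def estimate_alpha(
    e: np.ndarray, t: np.ndarray, p_e: np.ndarray, p_t: np.ndarray
) -> float:
    """Two-stage pseudo-likelihood estimate of the copula correlation.

    A coarse 41-point grid over [-0.99, 0.99] brackets the maximum, then a
    bounded 1-D optimizer refines it.
    """
    e = np.asarray(e, dtype=int)
    if e.size < 2:
        raise ValueError("alpha estimation requires at least 2 records")

    def negll(alpha: float) -> float:
        return -copula_loglik(e, t, p_e, p_t, alpha)

    alphas = np.linspace(-ALPHA_CAP, ALPHA_CAP, 41)
    vals = np.array([negll(a) for a in alphas])
    if not np.any(np.isfinite(vals)):
        raise ValueError("copula likelihood non-finite everywhere")
    i = int(np.argmin(vals))
    lo = alphas[max(i - 1, 0)]
    hi = alphas[min(i + 1, alphas.size - 1)]
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded")
    best = float(res.x) if res.fun <= vals[i] else float(alphas[i])
    return float(np.clip(best, -ALPHA_CAP, ALPHA_CAP))
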