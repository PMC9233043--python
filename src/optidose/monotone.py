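"""Isotonic (PAVA) monotonization of dose-response curves and the
Frechet-constrained adjustment of joint-probability curves.

Dose-efficacy and dose-toxicity relationships are assumed nondecreasing.
A model fitted on the 4-category joint outcome cannot carry that constraint
directly, so it is imposed post hoc: the marginal curves implied by the
predicted joint cells are projected onto nondecreasing sequences with the
pool-adjacent-violators algorithm (PAVA, unit weights per grid point), and
the predicted p11 is then re-chosen inside the Frechet interval
``[max(0, pE* + pT* - 1), min(pE*, pT*)]`` implied by the projected
marginals.  Two variants are offered:

``p11_only``
    clip the predicted p11 into the interval (minimizes |p11* - p11|);
``total_deviation``
    minimize the L1 deviation across all four cells.  With the remaining
    cells determined by (p11*, pE*, pT*), the objective is piecewise linear
    in p11*, so the exact minimizer is found by evaluating the interval
    endpoints and the four kink points; ties go to the smallest p11*.

The remaining cells follow sequentially: ``p10* = pE* - p11*``,
``p01* = pT* - p11*``, ``p00* = 1 - pE* - pT* + p11*``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import isotonic_regression

from .copula import frechet_bounds
from .utility import joint_marginals, validate_joint

__all__ = ["pava_nondecreasing", "adjust_joint_curve", "AdjustedJointCurve"]


def pava_nondecreasing(values: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted least-squares projection of a sequence onto nondecreasing
    sequences (pool-adjacent-violators)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a nonempty 1-D sequence")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != values.shape:
            raise ValueError("weights must match values in length")
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
    return np.asarray(isotonic_regression(values, weights=weights, increasing=True).x)


@dataclass
class AdjustedJointCurve:
    """Original and monotonized joint curve over a dose grid."""

    original: np.ndarray  # (D, 4)
    adjusted: np.ndarray  # (D, 4)
    p_e_star: np.ndarray  # (D,) PAVA-projected efficacy marginal
    p_t_star: np.ndarray  # (D,) PAVA-projected toxicity marginal


def _choose_p11_total_deviation(
    lo: np.ndarray, hi: np.ndarray, joint: np.ndarray, p_e_star: np.ndarray, p_t_star: np.ndarray
) -> np.ndarray:
    """Exact minimizer per grid point of the 4-term L1 objective, evaluated
    at interval endpoints and the kink points of the piecewise-linear
    objective, clipped into [lo, hi]; ties broken toward the smallest p11*."""
    p00, p10, p01, p11 = joint[:, 0], joint[:, 1], joint[:, 2], joint[:, 3]
    kinks = np.stack(
        [
            p11,
            p_e_star - p10,
            p_t_star - p01,
            p00 - (1.0 - p_e_star - p_t_star),
        ],
        axis=1,
    )
    cand = np.concatenate([lo[:, None], hi[:, None], np.clip(kinks, lo[:, None], hi[:, None])], axis=1)
    cand = np.sort(cand, axis=1)  # ascending so the first minimum is the smallest p11*
    t = cand
    obj = (
        np.abs(t - p11[:, None])
        + np.abs((p_e_star[:, None] - t) - p10[:, None])
        + np.abs((p_t_star[:, None] - t) - p01[:, None])
        + np.abs((1.0 - p_e_star[:, None] - p_t_star[:, None] + t) - p00[:, None])
    )
    # first index attaining (within 1e-12 of) the minimum -> smallest candidate
    best = obj.min(axis=1, keepdims=True)
    idx = np.argmax(obj <= best + 1e-12, axis=1)
    return t[np.arange(t.shape[0]), idx]


def adjust_joint_curve(
    joint_curve: np.ndarray,
    variant: Literal["p11_only", "total_deviation"] = "p11_only",
) -> AdjustedJointCurve:
    """Monotonize a joint-probability curve over a dose grid.

    ``joint_curve`` has shape (D, 4) in cell order (p00, p10, p01, p11),
    one row per (increasing) grid dose.  Idempotent: a curve whose
    marginals are already nondecreasing and whose p11 is feasible is
    returned unchanged.
    """
    joint_curve = validate_joint(joint_curve)
    if joint_curve.ndim != 2:
        raise ValueError("joint curve must have shape (D, 4)")
    p_e, p_t = joint_marginals(joint_curve)
    p_e_star = pava_nondecreasing(p_e)
    p_t_star = pava_nondecreasing(p_t)
    lo, hi = frechet_bounds(p_e_star, p_t_star)
    if variant == "p11_only":
        p11_star = np.clip(joint_curve[:, 3], lo, hi)
    elif variant == "total_deviation":
        p11_star = _choose_p11_total_deviation(lo, hi, joint_curve, p_e_star, p_t_star)
    else:
        raise ValueError(f"unknown adjustment variant {variant!r}")
    p10_star = p_e_star - p11_star
    p01_star = p_t_star - p11_star
    p00_star = 1.0 - p_e_star - p_t_star + p11_star
    adjusted = np.stack([p00_star, p10_star, p01_star, p11_star], axis=1)
    if adjusted.min() < -1e-12:
        raise FloatingPointError("adjusted joint cell fell below -1e-12")
    adjusted = np.clip(adjusted, 0.0, 1.0)
    return AdjustedJointCurve(
        original=joint_curve, adjusted=adjusted, p_e_star=p_e_star, p_t_star=p_t_star
    )
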