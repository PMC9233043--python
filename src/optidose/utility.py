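"""Utility matrices, utility functions, and dose-selection rules.

The clinical trade-off between a binary efficacy outcome E and a binary
toxicity outcome T is encoded by a 2x2 utility matrix assigning a numeric
desirability to each bivariate outcome.  The utility of a dose ``d`` for a
patient with covariates ``x`` is the expectation of that matrix under the
joint outcome distribution ``p(d, x) = (p00, p10, p01, p11)``::

    U(p, omega) = omega1*p00 + p10 + omega2*p11
                = omega1 + (1 - omega1)*pE - omega1*pT
                  + (omega1 + omega2 - 1)*p11

with ``pE = p10 + p11`` and ``pT = p01 + p11``.  When ``omega1 + omega2 = 1``
the ``p11`` term cancels and only the marginals matter.

Three selection rules are provided: a pointwise argmax over a dose grid for
a single joint-probability curve, the posterior-mean rule for Monte Carlo
draws of the curve, and the posterior-probability rule that maximizes the
probability of beating the utility at a population fixed dose.

Ties at the argmax are always broken toward the lowest dose (clinically
conservative).  Utilities are kept on the [0, 1] scale internally; reports
multiply by 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "UtilityMatrix",
    "UtilityConfig",
    "default_grid",
    "validate_grid",
    "validate_joint",
    "joint_marginals",
    "expected_utility",
    "utility_tox_cap",
    "utility_dose_penalty",
    "utility_profile",
    "select_dose_pointwise",
    "select_dose_posterior_mean",
    "select_dose_posterior_prob",
]

#: column order of every joint-probability array in the package
CELL_ORDER = ("p00", "p10", "p01", "p11")


@dataclass(frozen=True)
class UtilityMatrix:
    """2x2 outcome utilities ``u[T][E]`` for the bivariate binary outcome.

    The canonical two-parameter form fixes the best outcome (E=1, T=0) at 1
    and the worst (E=0, T=1) at 0, leaving ``omega1 = u00`` (neither) and
    ``omega2 = u11`` (both) as the elicited trade-off parameters.
    """

    u00: float
    u10: float
    u01: float
    u11: float

    def __post_init__(self) -> None:
        if not (self.u01 <= min(self.u00, self.u11) + 1e-12):
            raise ValueError("u01 must be the lowest utility")
        if not (max(self.u00, self.u11) <= self.u10 + 1e-12):
            raise ValueError("u10 must be the highest utility")

    @classmethod
    def from_omegas(cls, omega1: float, omega2: float) -> "UtilityMatrix":
        """Canonical (omega1, omega2) parameterization: (u00,u10,u01,u11) =
        (omega1, 1, 0, omega2) with both omegas in (0, 1)."""
        if not (0 < omega1 < 1 and 0 < omega2 < 1):
            raise ValueError("omega1 and omega2 must lie in (0, 1)")
        return cls(u00=omega1, u10=1.0, u01=0.0, u11=omega2)

    @classmethod
    def from_theta(cls, theta: float) -> "UtilityMatrix":
        """Legacy weighted-difference utility ``pE - theta*pT`` expressed as
        the matrix (0, 1, -theta, 1-theta), theta > 0."""
        if theta <= 0:
            raise ValueError("theta must be positive")
        return cls(u00=0.0, u10=1.0, u01=-theta, u11=1.0 - theta)

    @property
    def omega1(self) -> float:
        return self.u00

    @property
    def omega2(self) -> float:
        return self.u11

    def as_array(self) -> np.ndarray:
        """Utilities in the package cell order (p00, p10, p01, p11)."""
        return np.array([self.u00, self.u10, self.u01, self.u11])

    def shifted(self, c: float) -> "UtilityMatrix":
        """Add a constant to every cell (leaves the argmax dose unchanged)."""
        return UtilityMatrix(self.u00 + c, self.u10 + c, self.u01 + c, self.u11 + c)


@dataclass
class UtilityConfig:
    """A utility matrix plus the selection-rule modifiers.

    rule
        ``base``: plain expected utility.  ``tox_cap``: subtract
        ``tox_multiplier * omega1 * pT`` whenever ``pT >= tox_threshold``
        (inclusive), i.e. a tripling of the toxicity weight at the default
        multiplier of 2.  ``dose_penalty``: subtract ``delta*(d - d_fix)^2``.
    """

    matrix: UtilityMatrix = field(
        default_factory=lambda: UtilityMatrix.from_omegas(0.5, 0.5)
    )
    rule: Literal["base", "tox_cap", "dose_penalty"] = "base"
    tox_threshold: float = 0.3
    tox_multiplier: float = 2.0
    delta: float = 0.1
    d_fix: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.tox_threshold < 1):
            raise ValueError("tox_threshold must lie in (0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.tox_multiplier <= 0:
            raise ValueError("tox_multiplier must be positive")
        if self.rule == "dose_penalty" and self.d_fix is None:
            raise ValueError("dose_penalty rule requires d_fix")


def default_grid(n_points: int = 201, d_min: float = -1.0, d_max: float = 1.0) -> np.ndarray:
    """Equally spaced dose grid; the package default spans [-1, 1] with 201
    points (resolution 0.01)."""
    if n_points < 2:
        raise ValueError("grid needs at least 2 points")
    return np.linspace(d_min, d_max, n_points)


def validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("dose grid must be a 1-D array with >= 2 points")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("dose grid must be strictly increasing")
    return grid


def validate_joint(joint: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Check an array of joint probabilities (cells last axis, order
    p00,p10,p01,p11): all cells in [0,1] and rows summing to one."""
    joint = np.asarray(joint, dtype=float)
    if joint.shape[-1] != 4:
        raise ValueError("joint probabilities must have 4 cells on the last axis")
    if np.any(joint < -tol) or np.any(joint > 1 + tol):
        raise ValueError("joint cell probabilities must lie in [0, 1]")
    if np.any(np.abs(joint.sum(axis=-1) - 1.0) > tol):
        raise ValueError("joint cell probabilities must sum to 1")
    return joint


def joint_marginals(joint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (pE, pT) from a joint array."""
    joint = np.asarray(joint, dtype=float)
    return joint[..., 1] + joint[..., 3], joint[..., 2] + joint[..., 3]


def expected_utility(joint: np.ndarray, matrix: UtilityMatrix, *, validate: bool = True) -> np.ndarray:
    """Expected utility of the joint distribution(s) under a utility matrix.

    Vectorized over any leading axes; the last axis holds the 4 cells.
    """
    if validate:
        joint = validate_joint(joint)
    else:
        joint = np.asarray(joint, dtype=float)
    return joint @ matrix.as_array()


def utility_tox_cap(joint: np.ndarray, cfg: UtilityConfig, *, validate: bool = True) -> np.ndarray:
    """Toxicity-capped utility: base utility minus
    ``tox_multiplier * omega1 * pT`` when ``pT >= tox_threshold`` (inclusive
    at the threshold)."""
    base = expected_utility(joint, cfg.matrix, validate=validate)
    _, p_t = joint_marginals(joint)
    penalty = cfg.tox_multiplier * cfg.matrix.omega1 * p_t
    return base - np.where(p_t >= cfg.tox_threshold, penalty, 0.0)


def utility_dose_penalty(
    joint: np.ndarray, d: np.ndarray | float, cfg: UtilityConfig, *, validate: bool = True
) -> np.ndarray:
    """Dose-penalized utility: base utility minus ``delta*(d - d_fix)^2``."""
    if cfg.d_fix is None:
        raise ValueError("dose_penalty rule requires d_fix")
    base = expected_utility(joint, cfg.matrix, validate=validate)
    return base - cfg.delta * (np.asarray(d, dtype=float) - cfg.d_fix) ** 2


def utility_profile(
    joint_curve: np.ndarray, grid: np.ndarray, cfg: UtilityConfig, *, validate: bool = True
) -> np.ndarray:
    """Utility at every grid dose under the configured rule.

    ``joint_curve`` has shape (..., D, 4) aligned with ``grid`` of length D.
    """
    grid = validate_grid(grid)
    joint_curve = np.asarray(joint_curve, dtype=float)
    if joint_curve.shape[-2] != grid.size:
        raise ValueError("joint curve and dose grid lengths differ")
    if cfg.rule == "base":
        return expected_utility(joint_curve, cfg.matrix, validate=validate)
    if cfg.rule == "tox_cap":
        return utility_tox_cap(joint_curve, cfg, validate=validate)
    if cfg.rule == "dose_penalty":
        return utility_dose_penalty(joint_curve, grid, cfg, validate=validate)
    raise ValueError(f"unknown rule {cfg.rule!r}")


def _argmax_lowest(values: np.ndarray, axis: int = -1) -> np.ndarray:
    # np.argmax returns the first maximum; with a strictly increasing grid
    # that is the lowest dose among exact ties.
    return np.argmax(values, axis=axis)


def select_dose_pointwise(
    joint_curve: np.ndarray, grid: np.ndarray, cfg: UtilityConfig, *, validate: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise-optimal dose: grid argmax of the configured utility.

    Returns ``(dose, profile)``; vectorized over leading axes of
    ``joint_curve`` (shape (..., D, 4))."""
    profile = utility_profile(joint_curve, grid, cfg, validate=validate)
    idx = _argmax_lowest(profile, axis=-1)
    return np.asarray(grid)[idx], profile


def select_dose_posterior_mean(
    draws: np.ndarray, grid: np.ndarray, cfg: UtilityConfig, *, validate: bool = True
) -> tuple[float, np.ndarray]:
    """Posterior-mean rule: maximize the across-draw average utility.

    ``draws`` has shape (S, D, 4) for S posterior draws of the joint curve.
    Returns the selected dose and the S x D utility matrix.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3:
        raise ValueError("posterior draws must have shape (S, D, 4)")
    if draws.shape[0] < 1:
        raise ValueError("at least one posterior draw required")
    profile = utility_profile(draws, grid, cfg, validate=validate)
    idx = int(_argmax_lowest(profile.mean(axis=0)))
    return float(np.asarray(grid)[idx]), profile


def select_dose_posterior_prob(
    draws: np.ndarray, grid: np.ndarray, cfg: UtilityConfig, *, validate: bool = True
) -> tuple[float, np.ndarray]:
    """Posterior-probability rule: maximize ``P(U(d) > U(d_fix) | data)``.

    The comparison is strict, so the probability at ``d_fix`` itself is 0.
    ``d_fix`` is snapped to the nearest grid point if necessary (logged).
    Returns the selected dose and the per-dose probability profile.
    """
    if cfg.d_fix is None:
        raise ValueError("posterior-probability rule requires d_fix")
    grid = validate_grid(grid)
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3 or draws.shape[0] < 1:
        raise ValueError("posterior draws must have shape (S, D, 4) with S >= 1")
    fix_idx = int(np.argmin(np.abs(grid - cfg.d_fix)))
    if abs(grid[fix_idx] - cfg.d_fix) > 1e-12:
        logger.info(
            "d_fix=%.6g snapped to nearest grid dose %.6g", cfg.d_fix, grid[fix_idx]
        )
    profile = utility_profile(draws, grid, cfg, validate=validate)
    prob = (profile > profile[:, [fix_idx]]).mean(axis=0)
    idx = int(_argmax_lowest(prob))
    return float(grid[idx]), prob
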