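"""Random-forest models of the joint efficacy/toxicity distribution.

Two scikit-learn-style estimators:

``ForestJointModel``
    separate probability forests for E and T (optionally constrained to be
    nondecreasing in dose via the tree learner's monotonic-constraint
    facility), linked by a Gaussian copula whose correlation is estimated by
    pseudo-likelihood from out-of-bag (OOB) marginal probabilities, or by
    conditional independence.

``CategoricalForestModel``
    a single forest on the 4-level outcome (E,T) in {00,10,01,11}, with an
    optional post-hoc PAVA monotonization of the implied marginal curves.

Both expose ``predict_joint_curves(X_cov, grid)`` returning per-patient
joint-probability curves over a dose grid, the common currency of the dose
selection rules.  OOB probabilities are used whenever the training set
itself is scored (notably for the copula correlation estimate); fresh
patients use ordinary ensemble averaging.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_array, check_is_fitted

from .copula import CopulaSpec, estimate_alpha, joint_from_marginals
from .monotone import adjust_joint_curve
from .utility import validate_grid

logger = logging.getLogger(__name__)

__all__ = ["ForestJointModel", "CategoricalForestModel"]


def _check_xy(X, y):
    X = check_array(X, dtype=float)
    y = np.asarray(y)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be an (n, 2) array of binary (E, T) outcomes")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("E and T must be coded 0/1")
    if X.shape[0] < 20:
        raise ValueError("need at least 20 training rows")
    return X, y.astype(int)


def _curve_design(x_cov: np.ndarray, grid: np.ndarray, dose_idx: int, n_features: int) -> np.ndarray:
    """Stack (n_patients * n_doses, n_features) design rows with the dose
    column swept over the grid for every covariate row."""
    x_cov = np.atleast_2d(np.asarray(x_cov, dtype=float))
    if x_cov.shape[1] != n_features - 1:
        raise ValueError(
            f"expected {n_features - 1} covariates (dose excluded), got {x_cov.shape[1]}"
        )
    n, d = x_cov.shape[0], grid.size
    out = np.empty((n, d, n_features))
    cov_cols = [j for j in range(n_features) if j != dose_idx]
    out[:, :, cov_cols] = x_cov[:, None, :]
    out[:, :, dose_idx] = grid[None, :]
    return out.reshape(n * d, n_features)


class _ConstantClassifier:
    """Degenerate stand-in when a training outcome has a single class."""

    def __init__(self, rate: float, n: int):
        self.rate = rate
        self.oob = np.full(n, rate)

    def predict_p1(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.rate)


class _ForestWrapper:
    def __init__(self, est: RandomForestClassifier):
        self.est = est
        full = est.oob_decision_function_
        oob = full[:, list(est.classes_).index(1)].copy()
        # rows in every bootstrap sample have no OOB vote (nan or all-zero);
        # fall back to the in-sample ensemble probability for those rows
        bad = ~np.isfinite(oob) | (np.nansum(full, axis=1) <= 0)
        if bad.any():
            logger.debug("filling %d missing OOB probabilities in-sample", bad.sum())
            col = list(est.classes_).index(1)
            oob[bad] = est.predict_proba(est._X_fit[bad])[:, col]
        self.oob = oob

    def predict_p1(self, X: np.ndarray) -> np.ndarray:
        return self.est.predict_proba(X)[:, list(self.est.classes_).index(1)]


class ForestJointModel(BaseEstimator):
    """Marginal random forests for E and T linked by copula or independence.

    Parameters
    ----------
    joint : {"copula", "independence"}
        How the two fitted marginals are combined into the joint.  The
        copula correlation is estimated from OOB training probabilities.
    monotone : bool
        Constrain both forests to predict probabilities nondecreasing in
        dose (monotonic split constraint on the dose feature).
    dose_index : int
        Column of X holding the dose (default: last column).
    clip : float
        Predicted marginals are clipped to [clip, 1-clip] so the probit
        transform inside the copula stays finite.
    """

    def __init__(
        self,
        joint: str = "copula",
        monotone: bool = False,
        n_estimators: int = 500,
        min_samples_leaf: int = 1,
        max_features: str | int | float = "sqrt",
        dose_index: int = -1,
        clip: float = 1e-6,
        random_state: int | None = None,
    ):
        self.joint = joint
        self.monotone = monotone
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.dose_index = dose_index
        self.clip = clip
        self.random_state = random_state

    def _fit_one(self, X, labels, seed):
        if labels.min() == labels.max():
            rate = float(labels[0])
            logger.warning("constant outcome in training data; degenerate model")
            return _ConstantClassifier(rate, X.shape[0])
        cst = None
        if self.monotone:
            cst = np.zeros(X.shape[1], dtype=int)
            cst[self._dose_idx_] = 1
        est = RandomForestClassifier(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            oob_score=True,
            monotonic_cst=cst,
            random_state=seed,
        )
        est.fit(X, labels)
        est._X_fit = X
        return _ForestWrapper(est)

    def fit(self, X, y):
        if self.joint not in ("copula", "independence"):
            raise ValueError("joint must be 'copula' or 'independence'")
        X, y = _check_xy(X, y)
        self.n_features_in_ = X.shape[1]
        self._dose_idx_ = self.dose_index % self.n_features_in_
        rng = np.random.default_rng(self.random_state)
        seed_e, seed_t = rng.integers(0, 2**31 - 1, size=2)
        self.model_e_ = self._fit_one(X, y[:, 0], int(seed_e))
        self.model_t_ = self._fit_one(X, y[:, 1], int(seed_t))
        self.oob_p_e_ = np.clip(self.model_e_.oob, self.clip, 1 - self.clip)
        self.oob_p_t_ = np.clip(self.model_t_.oob, self.clip, 1 - self.clip)
        if self.joint == "copula":
            self.alpha_ = estimate_alpha(y[:, 0], y[:, 1], self.oob_p_e_, self.oob_p_t_)
            self.copula_ = CopulaSpec(alpha=self.alpha_, mode="copula")
        else:
            self.alpha_ = None
            self.copula_ = CopulaSpec(mode="independence")
        return self

    def predict_marginals(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Ensemble marginal probabilities (pE, pT) for fresh design rows
        (covariates + dose, same layout as training X)."""
        check_is_fitted(self, "model_e_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from training")
        p_e = np.clip(self.model_e_.predict_p1(X), self.clip, 1 - self.clip)
        p_t = np.clip(self.model_t_.predict_p1(X), self.clip, 1 - self.clip)
        return p_e, p_t

    def predict_marginal_curves(self, x_cov, grid) -> tuple[np.ndarray, np.ndarray]:
        """Per-patient marginal dose-response curves, shape (n, D) each."""
        check_is_fitted(self, "model_e_")
        grid = validate_grid(grid)
        x_cov = np.atleast_2d(np.asarray(x_cov, dtype=float))
        design = _curve_design(x_cov, grid, self._dose_idx_, self.n_features_in_)
        p_e, p_t = self.predict_marginals(design)
        shape = (x_cov.shape[0], grid.size)
        return p_e.reshape(shape), p_t.reshape(shape)

    def predict_joint_curves(self, x_cov, grid) -> np.ndarray:
        """Per-patient joint-probability curves, shape (n, D, 4)."""
        p_e, p_t = self.predict_marginal_curves(x_cov, grid)
        return joint_from_marginals(p_e, p_t, self.copula_)


class CategoricalForestModel(BaseEstimator):
    """Random forest on the 4-level joint outcome with optional PAVA.

    Parameters
    ----------
    pava : None | "p11_only" | "total_deviation"
        Post-hoc monotonization variant applied to every predicted curve.
    """

    #: class coding: label = E + 2*T, matching cell order (00, 10, 01, 11)
    N_CLASSES = 4

    def __init__(
        self,
        pava: str | None = None,
        n_estimators: int = 500,
        min_samples_leaf: int = 1,
        max_features: str | int | float = "sqrt",
        dose_index: int = -1,
        random_state: int | None = None,
    ):
        self.pava = pava
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.dose_index = dose_index
        self.random_state = random_state

    def fit(self, X, y):
        if self.pava not in (None, "p11_only", "total_deviation"):
            raise ValueError("pava must be None, 'p11_only' or 'total_deviation'")
        X, y = _check_xy(X, y)
        self.n_features_in_ = X.shape[1]
        self._dose_idx_ = self.dose_index % self.n_features_in_
        labels = y[:, 0] + 2 * y[:, 1]
        present = np.unique(labels)
        if present.size < self.N_CLASSES:
            logger.warning(
                "joint classes %s absent from training data; their predicted "
                "probability will be 0",
                sorted(set(range(self.N_CLASSES)) - set(present.tolist())),
            )
        self.est_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            random_state=self.random_state,
        )
        self.est_.fit(X, labels)
        return self

    def predict_joint(self, X) -> np.ndarray:
        """Joint cell probabilities (n, 4) for fresh design rows."""
        check_is_fitted(self, "est_")
        X = check_array(X, dtype=float)
        proba = self.est_.predict_proba(X)
        out = np.zeros((X.shape[0], self.N_CLASSES))
        for j, cls in enumerate(self.est_.classes_):
            out[:, int(cls)] = proba[:, j]
        return out

    def predict_joint_curves(self, x_cov, grid) -> np.ndarray:
        """Per-patient joint curves (n, D, 4), PAVA-adjusted if configured."""
        check_is_fitted(self, "est_")
        grid = validate_grid(grid)
        x_cov = np.atleast_2d(np.asarray(x_cov, dtype=float))
        design = _curve_design(x_cov, grid, self._dose_idx_, self.n_features_in_)
        joint = self.predict_joint(design).reshape(x_cov.shape[0], grid.size, 4)
        if self.pava is not None:
            joint = np.stack(
                [adjust_joint_curve(c, variant=self.pava).adjusted for c in joint]
            )
        return joint
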