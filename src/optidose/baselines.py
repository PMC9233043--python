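"""Population fixed-dose baseline.

A 4-category multinomial logistic regression of the joint outcome (E, T) on
dose alone.  Its utility-maximizing dose is the population fixed dose
``d_fix`` — the lower reference anchoring the percent-improvement metric
and the ``d_fix`` used by the dose-penalty and posterior-probability rules.

The fit uses L2-regularized multinomial logistic regression with a very
weak penalty (C=1e6, effectively the MLE) so that quasi-separation in small
samples cannot crash the fit.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .utility import UtilityConfig, utility_profile, validate_grid

__all__ = ["FixedDoseModel"]


class FixedDoseModel(BaseEstimator):
    """Dose-only multinomial model of the 4-level outcome (E, T).

    ``fit`` takes the dose vector and the (n, 2) binary outcome array;
    ``optimal_fixed_dose`` returns the grid dose maximizing the expected
    utility of the fitted cell probabilities (ties -> lowest dose).
    """

    N_CLASSES = 4

    def __init__(self, C: float = 1e6, max_iter: int = 2000):
        self.C = C
        self.max_iter = max_iter

    def fit(self, dose, y):
        dose = np.asarray(dose, dtype=float).reshape(-1, 1)
        y = np.asarray(y, dtype=int)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be an (n, 2) array of binary (E, T) outcomes")
        if dose.shape[0] < 50:
            raise ValueError("need at least 50 rows to fit the fixed-dose model")
        labels = y[:, 0] + 2 * y[:, 1]
        self.est_ = LogisticRegression(C=self.C, max_iter=self.max_iter)
        self.est_.fit(dose, labels)
        return self

    def predict_joint_curve(self, grid) -> np.ndarray:
        """Fitted joint cell probabilities over the dose grid, shape (D, 4)."""
        check_is_fitted(self, "est_")
        grid = validate_grid(grid)
        proba = self.est_.predict_proba(grid.reshape(-1, 1))
        out = np.zeros((grid.size, self.N_CLASSES))
        for j, cls in enumerate(self.est_.classes_):
            out[:, int(cls)] = proba[:, j]
        return out

    def optimal_fixed_dose(self, grid, cfg: UtilityConfig) -> float:
        """d_fix: grid argmax of the expected utility of the fitted cells."""
        grid = validate_grid(grid)
        profile = utility_profile(self.predict_joint_curve(grid), grid, cfg)
        return float(grid[int(np.argmax(profile))])
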