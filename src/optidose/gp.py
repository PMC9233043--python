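"""Bayesian Gaussian-process probit models for the joint (E, T) outcome.

Latent functions ``fE ~ GP(0, K_E)`` and ``fT ~ GP(0, K_T)`` over the input
``z = (x, d)`` drive the marginals through a probit link::

    Pr(E=0) = Phi(fE + a),   Pr(T=0) = Phi(fT + b)

and the 4-cell joint is formed either under conditional independence or a
Gaussian copula, giving a multinomial likelihood.  The kernel is a Gaussian
ARD kernel

    k(z_i, z_j) = eta^2 exp( -1/2 sum_q rho_q^2 (z_i^q - z_j^q)^2 )

in which ``rho_q`` acts as an inverse length-scale: a small ``rho_q`` makes
the covariance nearly independent of input q, softly removing it.  The
``rho_q`` receive a horseshoe prior ``rho_q ~ N(0, lambda_q^2 tau^2)`` with
half-Cauchy(0,1) local scales ``lambda_q`` and global scale ``tau``;
intercepts a, b are standard normal and the signal magnitudes eta are
half-normal(0,1).

Posterior sampling uses a blocked MCMC scheme: the latents are whitened
(``f = L u`` with ``K = L L^T`` and ``u ~ N(0, I)``) and updated by
elliptical slice sampling; kernel hyperparameters, intercepts, horseshoe
scales and the copula correlation get per-coordinate adaptive random-walk
Metropolis (adaptation during warmup only).  Positive parameters are
sampled on the log scale with the Jacobian included.

Posterior predictive joint curves over a dose grid draw the latent at the
new inputs from the full Gaussian conditional given each draw's training
latents and hyperparameters, propagating posterior uncertainty into the
dose-selection rules.  Inputs are standardized by training statistics
before kernel evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .copula import bvn_cdf
from .utility import validate_grid

logger = logging.getLogger(__name__)

__all__ = ["ard_kernel", "GPJointModel", "PosteriorProbDraws"]


def ard_kernel(z_i: np.ndarray, z_j: np.ndarray, eta: float, rho: np.ndarray) -> float:
    """Gaussian ARD kernel between two input vectors."""
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if z_i.shape != z_j.shape or z_i.shape != rho.shape:
        raise ValueError("z_i, z_j and rho must share one dimension")
    return float(eta**2 * np.exp(-0.5 * np.sum(rho**2 * (z_i - z_j) ** 2)))


def _kernel_matrix(dsq: np.ndarray, eta: float, rho: np.ndarray, jitter: float) -> np.ndarray:
    """K from precomputed per-dimension squared distances dsq (P, n, n)."""
    m = np.tensordot(rho**2, dsq, axes=1)
    k = eta**2 * np.exp(-0.5 * m)
    k[np.diag_indices_from(k)] += jitter
    return k


def _cross_kernel(z_a: np.ndarray, z_b: np.ndarray, eta: float, rho: np.ndarray) -> np.ndarray:
    d = z_a[:, None, :] - z_b[None, :, :]
    return eta**2 * np.exp(-0.5 * np.einsum("q,ijq->ij", rho**2, d**2))


def _chol_jittered(mat: np.ndarray, jitter: float, max_jitter: float = 1e-4) -> np.ndarray:
    j = jitter
    while True:
        try:
            return cholesky(mat + j * np.eye(mat.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            j *= 10.0
            if j > max_jitter:
                raise


@dataclass
class PosteriorProbDraws:
    """Monte Carlo draws of the joint-probability curve over a dose grid.

    ``joint`` has shape (S, D, 4); ``alpha`` holds the per-draw copula
    correlation (zeros under independence).
    """

    grid: np.ndarray
    joint: np.ndarray
    alpha: np.ndarray


class _ChainState:
    """One chain's current state plus cached Cholesky factors and latents."""

    def __init__(self, n: int, p: int, a0: float, b0: float, copula: bool):
        self.u_e = np.zeros(n)
        self.u_t = np.zeros(n)
        self.a = a0
        self.b = b0
        self.log_eta = {"E": 0.0, "T": 0.0}
        self.rho = {"E": np.full(p, 0.3), "T": np.full(p, 0.3)}
        self.log_lam = {"E": np.zeros(p), "T": np.zeros(p)}
        self.log_tau = {"E": 0.0, "T": 0.0}
        self.gamma = 0.0 if copula else None
        self.chol = {}  # outcome -> lower Cholesky of K
        self.f = {}  # outcome -> L @ u


def _log_half_cauchy(x: float | np.ndarray) -> np.ndarray:
    return -np.log1p(np.asarray(x) ** 2)  # up to a constant


class GPJointModel(BaseEstimator):
    """GP probit model of the joint (E, T) outcome with MCMC inference.

    Parameters
    ----------
    mode : {"independence", "copula"}
        Joint construction in the multinomial likelihood.  Independence is
        the default; the copula variant additionally samples the copula
        correlation (parameterized alpha = tanh(gamma), gamma ~ N(0,1)).
    n_chains, n_warmup, n_samples : int
        MCMC configuration; defaults sized for test-scale problems.
    dose_index : int
        Column of X holding the dose.
    jitter : float
        Diagonal jitter added to every kernel matrix (escalated up to 1e-4
        in the predictive step if a Cholesky fails).
    """

    def __init__(
        self,
        mode: str = "independence",
        n_chains: int = 2,
        n_warmup: int = 500,
        n_samples: int = 500,
        dose_index: int = -1,
        jitter: float = 1e-6,
        random_state: int | None = None,
    ):
        self.mode = mode
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.dose_index = dose_index
        self.jitter = jitter
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        if self.mode not in ("independence", "copula"):
            raise ValueError("mode must be 'independence' or 'copula'")
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if y.ndim != 2 or y.shape[1] != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("y must be an (n, 2) array of binary (E, T) outcomes")
        n, p = X.shape
        if n > 500:
            raise ValueError("dense GP inference is limited to n <= 500")
        self.n_features_in_ = p
        self._dose_idx_ = self.dose_index % p
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self.z_train_ = (X - self.mean_) / self.scale_
        self.y_ = y
        self._dsq_ = np.stack(
            [(self.z_train_[:, q, None] - self.z_train_[None, :, q]) ** 2 for q in range(p)]
        )
        rng = np.random.default_rng(self.random_state)
        chains = []
        for _ in range(self.n_chains):
            chains.append(self._run_chain(np.random.default_rng(rng.integers(2**31 - 1))))
        # stack draws: dict name -> (chains, samples, ...)
        self.draws_ = {
            k: np.stack([c[k] for c in chains]) for k in chains[0]
        }
        self._compute_diagnostics()
        return self

    # ------------------------------------------------------- log densities

    def _loglik(self, f_e: np.ndarray, f_t: np.ndarray, a: float, b: float, gamma) -> float:
        q_e = ndtr(f_e + a)  # Pr(E=0)
        q_t = ndtr(f_t + b)
        if gamma is None:
            p00 = q_e * q_t
        else:
            p00 = bvn_cdf(f_e + a, f_t + b, float(np.tanh(gamma)))
            p00 = np.clip(p00, np.maximum(0.0, q_e + q_t - 1.0), np.minimum(q_e, q_t))
        e, t = self.y_[:, 0], self.y_[:, 1]
        cells = np.where(
            (e == 0) & (t == 0), p00,
            np.where(
                (e == 1) & (t == 0), q_t - p00,
                np.where((e == 0) & (t == 1), q_e - p00, 1.0 - q_e - q_t + p00),
            ),
        )
        return float(np.sum(np.log(np.maximum(cells, 1e-12))))

    def _state_loglik(self, st: _ChainState) -> float:
        return self._loglik(st.f["E"], st.f["T"], st.a, st.b, st.gamma)

    @staticmethod
    def _log_prior_rho(st: _ChainState, o: str) -> float:
        scale = np.exp(st.log_lam[o] + st.log_tau[o])
        return float(np.sum(-0.5 * (st.rho[o] / scale) ** 2 - np.log(scale)))

    # ------------------------------------------------------------- sampler

    def _refresh_kernel(self, st: _ChainState, o: str) -> None:
        k = _kernel_matrix(self._dsq_, np.exp(st.log_eta[o]), st.rho[o], self.jitter)
        st.chol[o] = cholesky(k, lower=True)
        u = st.u_e if o == "E" else st.u_t
        st.f[o] = st.chol[o] @ u

    def _ess_update(self, st: _ChainState, o: str, rng: np.random.Generator) -> None:
        """Elliptical slice sampling of the whitened latent for outcome o."""
        u = st.u_e if o == "E" else st.u_t
        nu = rng.standard_normal(u.size)
        log_y = self._state_loglik(st) + np.log(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        lo, hi = theta - 2.0 * np.pi, theta
        for _ in range(100):
            u_new = u * np.cos(theta) + nu * np.sin(theta)
            f_new = st.chol[o] @ u_new
            f_e = f_new if o == "E" else st.f["E"]
            f_t = f_new if o == "T" else st.f["T"]
            if self._loglik(f_e, f_t, st.a, st.b, st.gamma) > log_y:
                if o == "E":
                    st.u_e = u_new
                else:
                    st.u_t = u_new
                st.f[o] = f_new
                return
            if theta < 0:
                lo = theta
            else:
                hi = theta
            theta = rng.uniform(lo, hi)
        # ellipse fully below the slice within the iteration cap: keep state

    def _mh(self, key, get, setv, logpost, scales, accepts, trials, rng, adapt, it):
        """Generic per-coordinate adaptive random-walk Metropolis step."""
        cur = get()
        lp0 = logpost()
        prop = cur + np.exp(scales[key]) * rng.standard_normal()
        setv(prop)
        lp1 = logpost()
        trials[key] += 1
        if np.log(rng.uniform()) < lp1 - lp0:
            accepts[key] += 1
            accepted = True
        else:
            setv(cur)
            accepted = False
        if adapt:
            scales[key] += ((1.0 if accepted else 0.0) - 0.44) / max(it, 10) ** 0.6
        return accepted

    def _run_chain(self, rng: np.random.Generator) -> dict:
        n, p = self.z_train_.shape
        e, t = self.y_[:, 0], self.y_[:, 1]
        a0 = float(ndtri(np.clip(np.mean(e == 0), 0.02, 0.98)))
        b0 = float(ndtri(np.clip(np.mean(t == 0), 0.02, 0.98)))
        st = _ChainState(n, p, a0, b0, copula=(self.mode == "copula"))
        for o in ("E", "T"):
            self._refresh_kernel(st, o)
        scales: dict = {}
        accepts: dict = {}
        trials: dict = {}

        def reg(key, s0=-1.0):
            scales[key] = s0
            accepts[key] = 0
            trials[key] = 0

        for o in ("E", "T"):
            reg(("eta", o))
            reg(("tau", o))
            for q in range(p):
                reg(("rho", o, q))
                reg(("lam", o, q))
        reg("a", -2.0)
        reg("b", -2.0)
        if st.gamma is not None:
            reg("gamma")

        keep: dict[str, list] = {
            "u_e": [], "u_t": [], "a": [], "b": [],
            "eta_e": [], "eta_t": [], "rho_e": [], "rho_t": [],
            "lam_e": [], "lam_t": [], "tau_e": [], "tau_t": [], "alpha": [],
        }
        total = self.n_warmup + self.n_samples
        for it in range(1, total + 1):
            adapt = it <= self.n_warmup
            self._ess_update(st, "E", rng)
            self._ess_update(st, "T", rng)

            for o in ("E", "T"):
                # signal magnitude (log scale; half-normal prior + Jacobian)
                def lp_eta(o=o):
                    eta = np.exp(st.log_eta[o])
                    return self._state_loglik(st) - 0.5 * eta**2 + st.log_eta[o]

                def set_eta(v, o=o):
                    st.log_eta[o] = v
                    self._refresh_kernel(st, o)

                self._mh(("eta", o), lambda o=o: st.log_eta[o], set_eta, lp_eta,
                         scales, accepts, trials, rng, adapt, it)

                # ARD weights (normal prior with horseshoe scales)
                for q in range(p):
                    def lp_rho(o=o):
                        return self._state_loglik(st) + self._log_prior_rho(st, o)

                    def set_rho(v, o=o, q=q):
                        st.rho[o][q] = v
                        self._refresh_kernel(st, o)

                    self._mh(("rho", o, q), lambda o=o, q=q: st.rho[o][q], set_rho,
                             lp_rho, scales, accepts, trials, rng, adapt, it)

                # horseshoe scales: only the rho prior + half-Cauchy densities
                # depend on them, so no kernel rebuild is needed
                for q in range(p):
                    def lp_lam(o=o, q=q):
                        lam = np.exp(st.log_lam[o][q])
                        return (self._log_prior_rho(st, o)
                                + float(_log_half_cauchy(lam)) + st.log_lam[o][q])

                    def set_lam(v, o=o, q=q):
                        st.log_lam[o][q] = v

                    self._mh(("lam", o, q), lambda o=o, q=q: st.log_lam[o][q],
                             set_lam, lp_lam, scales, accepts, trials, rng, adapt, it)

                def lp_tau(o=o):
                    tau = np.exp(st.log_tau[o])
                    return (self._log_prior_rho(st, o)
                            + float(_log_half_cauchy(tau)) + st.log_tau[o])

                def set_tau(v, o=o):
                    st.log_tau[o] = v

                self._mh(("tau", o), lambda o=o: st.log_tau[o], set_tau, lp_tau,
                         scales, accepts, trials, rng, adapt, it)

            # intercepts (standard normal priors; likelihood only)
            def lp_a():
                return self._state_loglik(st) - 0.5 * st.a**2

            def set_a(v):
                st.a = v

            self._mh("a", lambda: st.a, set_a, lp_a, scales, accepts, trials, rng, adapt, it)

            def lp_b():
                return self._state_loglik(st) - 0.5 * st.b**2

            def set_b(v):
                st.b = v

            self._mh("b", lambda: st.b, set_b, lp_b, scales, accepts, trials, rng, adapt, it)

            if st.gamma is not None:
                def lp_g():
                    return self._state_loglik(st) - 0.5 * st.gamma**2

                def set_g(v):
                    st.gamma = v

                self._mh("gamma", lambda: st.gamma, set_g, lp_g, scales, accepts,
                         trials, rng, adapt, it)

            if it > self.n_warmup:
                keep["u_e"].append(st.u_e.copy())
                keep["u_t"].append(st.u_t.copy())
                keep["a"].append(st.a)
                keep["b"].append(st.b)
                keep["eta_e"].append(np.exp(st.log_eta["E"]))
                keep["eta_t"].append(np.exp(st.log_eta["T"]))
                keep["rho_e"].append(st.rho["E"].copy())
                keep["rho_t"].append(st.rho["T"].copy())
                keep["lam_e"].append(np.exp(st.log_lam["E"]))
                keep["lam_t"].append(np.exp(st.log_lam["T"]))
                keep["tau_e"].append(np.exp(st.log_tau["E"]))
                keep["tau_t"].append(np.exp(st.log_tau["T"]))
                keep["alpha"].append(np.tanh(st.gamma) if st.gamma is not None else 0.0)
        return {k: np.asarray(v) for k, v in keep.items()}

    # --------------------------------------------------------- diagnostics

    def _compute_diagnostics(self) -> None:
        import arviz as az

        scalars = {k: self.draws_[k] for k in ("a", "b", "eta_e", "eta_t", "tau_e", "tau_t")}
        ds = az.convert_to_dataset(scalars)
        rhat = az.rhat(ds)
        ess = az.ess(ds)
        self.rhat_ = {k: float(rhat[k].values) for k in scalars}
        self.ess_ = {k: float(ess[k].values) for k in scalars}
        bad = {k: v for k, v in self.rhat_.items() if np.isfinite(v) and v > 1.2}
        if bad:
            logger.warning("MCMC convergence warning, R-hat > 1.2: %s", bad)

    # ---------------------------------------------------------- prediction

    def _flat_draws(self, max_draws: int | None, rng: np.random.Generator):
        flat = {k: v.reshape(-1, *v.shape[2:]) for k, v in self.draws_.items()}
        s = flat["a"].size
        if max_draws is not None and max_draws < s:
            idx = np.sort(rng.choice(s, size=max_draws, replace=False))
            flat = {k: v[idx] for k, v in flat.items()}
        return flat

    def posterior_joint_draws(
        self,
        x_cov: np.ndarray,
        grid: np.ndarray,
        max_draws: int | None = None,
        random_state: int | None = None,
    ) -> PosteriorProbDraws:
        """Posterior predictive joint-probability curves for one patient.

        For every retained posterior draw, the latent functions at the new
        inputs (x_cov paired with each grid dose) are sampled from the full
        Gaussian conditional given that draw's training latents and
        hyperparameters, then pushed through the probit link and joint
        construction.
        """
        check_is_fitted(self, "draws_")
        grid = validate_grid(grid)
        x_cov = np.asarray(x_cov, dtype=float).ravel()
        if x_cov.size != self.n_features_in_ - 1:
            raise ValueError("x_cov must hold the covariates without the dose")
        z_new = np.empty((grid.size, self.n_features_in_))
        cov_cols = [j for j in range(self.n_features_in_) if j != self._dose_idx_]
        z_new[:, cov_cols] = x_cov[None, :]
        z_new[:, self._dose_idx_] = grid
        z_new = (z_new - self.mean_) / self.scale_

        rng = np.random.default_rng(random_state)
        flat = self._flat_draws(max_draws, rng)
        s = flat["a"].size
        d = grid.size
        joint = np.empty((s, d, 4))
        for i in range(s):
            f_star = {}
            for o, (u_key, eta_key, rho_key) in {
                "E": ("u_e", "eta_e", "rho_e"),
                "T": ("u_t", "eta_t", "rho_t"),
            }.items():
                eta = float(flat[eta_key][i])
                rho = flat[rho_key][i]
                u = flat[u_key][i]
                k_train = _kernel_matrix(self._dsq_, eta, rho, self.jitter)
                chol_l = _chol_jittered(k_train, 0.0, max_jitter=1e-4)
                k_star = _cross_kernel(self.z_train_, z_new, eta, rho)
                k_ss = _cross_kernel(z_new, z_new, eta, rho)
                a_mat = solve_triangular(chol_l, k_star, lower=True)
                mean = a_mat.T @ u  # k*' K^-1 f with f = L u
                cov = k_ss - a_mat.T @ a_mat
                chol_s = _chol_jittered(cov, self.jitter)
                f_star[o] = mean + chol_s @ rng.standard_normal(d)
            g_e = f_star["E"] + flat["a"][i]
            g_t = f_star["T"] + flat["b"][i]
            q_e = ndtr(g_e)
            q_t = ndtr(g_t)
            if self.mode == "copula":
                p00 = bvn_cdf(g_e, g_t, float(flat["alpha"][i]))
                p00 = np.clip(p00, np.maximum(0.0, q_e + q_t - 1.0), np.minimum(q_e, q_t))
            else:
                p00 = q_e * q_t
            joint[i, :, 0] = p00
            joint[i, :, 1] = q_t - p00
            joint[i, :, 2] = q_e - p00
            joint[i, :, 3] = 1.0 - q_e - q_t + p00
        joint = np.clip(joint, 0.0, 1.0)
        return PosteriorProbDraws(grid=grid, joint=joint, alpha=np.asarray(flat["alpha"]))

    def posterior_joint_draws_batch(
        self,
        x_cov: np.ndarray,
        grid: np.ndarray,
        max_draws: int | None = None,
        random_state: int | None = None,
    ) -> np.ndarray:
        """Posterior predictive joint curves for many patients at once.

        Returns an array of shape (S, n_patients, D, 4).  The per-draw
        training Cholesky is computed once and shared across patients;
        each patient's grid latent is drawn from its own D-dimensional
        Gaussian conditional.
        """
        check_is_fitted(self, "draws_")
        grid = validate_grid(grid)
        x_cov = np.atleast_2d(np.asarray(x_cov, dtype=float))
        if x_cov.shape[1] != self.n_features_in_ - 1:
            raise ValueError("x_cov must hold the covariates without the dose")
        n_pat, d = x_cov.shape[0], grid.size
        cov_cols = [j for j in range(self.n_features_in_) if j != self._dose_idx_]
        z_new = np.empty((n_pat, d, self.n_features_in_))
        z_new[:, :, cov_cols] = x_cov[:, None, :]
        z_new[:, :, self._dose_idx_] = grid[None, :]
        z_new = (z_new - self.mean_) / self.scale_
        z_flat = z_new.reshape(n_pat * d, self.n_features_in_)

        rng = np.random.default_rng(random_state)
        flat = self._flat_draws(max_draws, rng)
        s = flat["a"].size
        joint = np.empty((s, n_pat, d, 4))
        for i in range(s):
            g = {}
            for o, (u_key, eta_key, rho_key, icpt) in {
                "E": ("u_e", "eta_e", "rho_e", "a"),
                "T": ("u_t", "eta_t", "rho_t", "b"),
            }.items():
                eta = float(flat[eta_key][i])
                rho = flat[rho_key][i]
                u = flat[u_key][i]
                k_train = _kernel_matrix(self._dsq_, eta, rho, self.jitter)
                chol_l = _chol_jittered(k_train, 0.0, max_jitter=1e-4)
                k_star = _cross_kernel(self.z_train_, z_flat, eta, rho)
                a_mat = solve_triangular(chol_l, k_star, lower=True)
                mean = (a_mat.T @ u).reshape(n_pat, d)
                a_blk = a_mat.reshape(-1, n_pat, d)
                f_star = np.empty((n_pat, d))
                for j in range(n_pat):
                    k_ss = _cross_kernel(z_new[j], z_new[j], eta, rho)
                    cov = k_ss - a_blk[:, j, :].T @ a_blk[:, j, :]
                    chol_s = _chol_jittered(cov, self.jitter)
                    f_star[j] = mean[j] + chol_s @ rng.standard_normal(d)
                g[o] = f_star + float(flat[icpt][i])
            q_e = ndtr(g["E"])
            q_t = ndtr(g["T"])
            if self.mode == "copula":
                p00 = bvn_cdf(g["E"], g["T"], float(flat["alpha"][i]))
                p00 = np.clip(p00, np.maximum(0.0, q_e + q_t - 1.0), np.minimum(q_e, q_t))
            else:
                p00 = q_e * q_t
            joint[i, :, :, 0] = p00
            joint[i, :, :, 1] = q_t - p00
            joint[i, :, :, 2] = q_e - p00
            joint[i, :, :, 3] = 1.0 - q_e - q_t + p00
        return np.clip(joint, 0.0, 1.0)

    def posterior_marginals_at_train(self) -> tuple[np.ndarray, np.ndarray]:
        """Posterior-mean marginal probabilities (pE, pT) at the training
        inputs — convenience for recovery checks.

        Reconstructs f = L u per draw from the stored whitened latents.
        """
        check_is_fitted(self, "draws_")
        flat = self._flat_draws(None, np.random.default_rng(0))
        s = flat["a"].size
        p_e = np.zeros(self.z_train_.shape[0])
        p_t = np.zeros(self.z_train_.shape[0])
        for i in range(s):
            for o, (u_key, eta_key, rho_key, icpt), out in (
                ("E", ("u_e", "eta_e", "rho_e", "a"), p_e),
                ("T", ("u_t", "eta_t", "rho_t", "b"), p_t),
            ):
                k = _kernel_matrix(self._dsq_, float(flat[eta_key][i]), flat[rho_key][i], self.jitter)
                f = cholesky(k, lower=True) @ flat[u_key][i]
                out += 1.0 - ndtr(f + flat[icpt][i])
        return p_e / s, p_t / s
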