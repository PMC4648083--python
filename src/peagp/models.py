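"""Marker-based genomic prediction models.

Five whole-genome regression methods, each exposing marker effects so that a
genomic estimated breeding value (GEBV) for any genotyped individual is
``intercept + centered codes . effects``:

* :class:`GBLUP` — mixed model y = 1 mu + u + e with u ~ N(0, G sigma_u^2),
  G the VanRaden relationship matrix; variance components by REML on the
  eigendecomposition of G; equivalent ridge/marker-effect form exposed.
* :class:`BayesMarkerRegression` — Gibbs sampler with per-marker effect
  variances (scaled inverse chi-square prior).  ``pi = 0`` is BayesA; a
  positive ``pi`` puts a point mass of zero effects (BayesB).
* :class:`MarkerLasso` — L1-penalized regression by cyclic coordinate
  descent with warm starts along a decreasing penalty grid; the penalty is
  tuned by 10-fold cross-validation minimizing MSEP.
* :class:`KernelPLS` — univariate partial least squares computed with the
  kernel algorithm (deflation on W W'); the number of latent components is
  tuned by 10-fold cross-validation.

All estimators follow scikit-learn conventions (``fit`` / ``predict``,
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) and can be used inside sklearn model-selection utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import GenotypeMatrix, RelationshipMatrix

__all__ = [
    "GBLUP",
    "BayesMarkerRegression",
    "MarkerLasso",
    "KernelPLS",
    "TuningResult",
    "tune_by_cv",
    "FittedModel",
    "fit_gblup",
    "fit_bayes",
    "fit_lasso",
    "fit_kplsr",
    "predict_gebv",
    "make_model",
]


# --------------------------------------------------------------------------
# cross-validation tuning
# --------------------------------------------------------------------------


@dataclass
class TuningResult:
    """Grid, per-candidate mean 10-fold MSEP, and the selected candidate."""

    grid: np.ndarray
    msep: np.ndarray
    selected: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        self.msep = np.asarray(self.msep, dtype=float)


def cv_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Deterministic fold labels: shuffled positions taken modulo `folds`."""
    rng = np.random.default_rng(seed)
    lab = np.empty(n, dtype=int)
    lab[rng.permutation(n)] = np.arange(n) % folds
    return lab


def tune_by_cv(fit_fn, y, X, grid, folds: int = 10, seed: int = 0) -> TuningResult:
    """Select the grid candidate minimizing mean held-out MSEP.

    ``fit_fn(candidate, X_train, y_train)`` must return an object with a
    ``predict`` method.  Exact ties go to the earlier grid entry, so grids
    should be ordered from the simplest model to the most complex (largest
    penalty first, smallest component count first).
    """
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("empty tuning grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"need at least {folds} observations for {folds}-fold CV")
    lab = cv_folds(n, folds, seed)
    msep = np.zeros(len(grid))
    for f in range(folds):
        tr, te = lab != f, lab == f
        for gi, cand in enumerate(grid):
            model = fit_fn(cand, X[tr], y[tr])
            pred = model.predict(X[te])
            msep[gi] += float(np.mean((pred - y[te]) ** 2))
    msep /= folds
    return TuningResult(grid=np.asarray(grid), msep=msep, selected=grid[int(np.argmin(msep))])


# --------------------------------------------------------------------------
# GBLUP
# --------------------------------------------------------------------------


class GBLUP(RegressorMixin, BaseEstimator):
    """Genomic BLUP with REML variance components.

    Parameters
    ----------
    ratio : float or None
        Fixed variance ratio lambda = sigma_e^2 / sigma_u^2.  ``None`` (the
        default) estimates it by REML, profiling the restricted likelihood
        on the eigendecomposition of G.
    """

    def __init__(self, ratio: float | None = None):
        self.ratio = ratio

    def fit(self, X, y, G: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n != len(y):
            raise ValueError("X and y lengths differ")
        if n < 2:
            raise ValueError("need at least 2 observations")
        freqs = X.mean(axis=0) / 2.0
        self.center_ = 2.0 * freqs
        W = X - self.center_
        poly = (freqs > 0) & (freqs < 1)
        denom = 2.0 * np.sum(freqs[poly] * (1.0 - freqs[poly]))
        if G is None:
            if denom <= 0:
                raise ValueError("no polymorphic markers")
            G = W[:, poly] @ W[:, poly].T / denom

        s, U = np.linalg.eigh((G + G.T) / 2.0)
        s = np.clip(s, 0.0, None)
        yt = U.T @ y
        xt = U.T @ np.ones(n)

        if np.var(y) == 0.0:
            self._degenerate(X, y)
            return self

        if self.ratio is None:
            lam = self._reml(s, xt, yt, n)
        else:
            lam = float(self.ratio)
            if lam <= 0:
                raise ValueError("ratio must be > 0")
        w = s + lam
        mu = float(np.sum(xt * yt / w) / np.sum(xt**2 / w))
        resid_rot = yt - xt * mu
        var_u = float(np.sum(resid_rot**2 / w) / (n - 1))
        self.var_u_ = var_u
        self.var_e_ = lam * var_u
        self.lambda_ = lam
        # genomic heritability: per-individual genetic variance is
        # var_u * G_ii, and inbred panels have mean diagonal ~ 2
        gbar = float(np.mean(np.diag(G)))
        self.h2_ = gbar / (gbar + lam)
        self.mu_ = mu
        alpha_rot = resid_rot / w  # U' (G + lam I)^-1 (y - mu)
        alpha = U @ alpha_rot
        self._alpha_ = alpha
        self.gebv_ = G @ alpha
        # marker-effect back-solution (ridge-equivalent form)
        coef = np.zeros(p)
        if denom > 0:
            coef[poly] = W[:, poly].T @ alpha / denom
        self.coef_ = coef
        self.intercept_ = mu - self.center_ @ coef
        self.n_features_in_ = p
        return self

    def _degenerate(self, X, y):
        self.coef_ = np.zeros(X.shape[1])
        self.mu_ = float(y[0]) if len(y) else 0.0
        self.intercept_ = self.mu_
        self.var_u_ = 0.0
        self.var_e_ = 0.0
        self.lambda_ = np.inf
        self.h2_ = 0.0
        self.gebv_ = np.zeros(len(y))
        self.n_features_in_ = X.shape[1]

    @staticmethod
    def _reml(s, xt, yt, n):
        """Profiled REML over log lambda, lambda = var_e / var_u."""

        def neg_restricted_ll(log_lam):
            w = s + np.exp(log_lam)
            sxx = np.sum(xt**2 / w)
            mu = np.sum(xt * yt / w) / sxx
            r2 = np.sum((yt - xt * mu) ** 2 / w)
            return (n - 1) * np.log(r2) + np.sum(np.log(w)) + np.log(sxx)

        res = minimize_scalar(neg_restricted_ll, bounds=(-10.0, 12.0), method="bounded")
        if not res.success:
            raise RuntimeError(f"REML did not converge: {res}")
        return float(np.exp(res.x))

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict_kinship(self, X_test, X_train):
        """Predict through the kinship (G-matrix) form instead of marker effects."""
        check_is_fitted(self, "_alpha_")
        Wte = np.asarray(X_test, dtype=float) - self.center_
        Wtr = np.asarray(X_train, dtype=float) - self.center_
        freqs = self.center_ / 2.0
        poly = (freqs > 0) & (freqs < 1)
        denom = 2.0 * np.sum(freqs[poly] * (1.0 - freqs[poly]))
        G_cross = Wte[:, poly] @ Wtr[:, poly].T / denom
        return self.mu_ + G_cross @ self._alpha_


# --------------------------------------------------------------------------
# Bayesian marker regression (BayesA / BayesB)
# --------------------------------------------------------------------------


@njit(cache=True)
def _gibbs_core(W, y, wtw, pi, n_iter, burnin, thin, nu, S, nu_e, S_e, seed):
    np.random.seed(seed)
    n, p = W.shape
    beta = np.zeros(p)
    delta = np.ones(p)
    sigma2 = np.full(p, S)
    mu = y.mean()
    e = y - mu
    for j in range(p):
        e -= W[:, j] * beta[j]
    var_y = y.var()
    sigma_e = var_y / 2.0 if var_y > 0 else 1.0

    n_keep = 0
    beta_sum = np.zeros(p)
    delta_sum = np.zeros(p)
    mu_sum = 0.0
    se_sum = 0.0
    log_prior_odds = np.log((1.0 - pi) / pi) if pi > 0.0 else 0.0

    for it in range(n_iter):
        for j in range(p):
            v = wtw[j]
            if v <= 0.0:
                beta[j] = 0.0
                continue
            rhs = np.dot(W[:, j], e) + v * beta[j]
            # per-marker variance
            if pi == 0.0 or delta[j] == 1.0:
                df = nu + 1.0
                sc = (nu * S + beta[j] * beta[j]) / df
            else:
                df = nu
                sc = S
            sigma2[j] = df * sc / np.random.chisquare(df)
            old = beta[j]
            if pi > 0.0:
                s2 = sigma2[j]
                log_bf = (
                    -0.5 * np.log(1.0 + v * s2 / sigma_e)
                    + 0.5 * rhs * rhs * s2 / (sigma_e * (sigma_e + v * s2))
                )
                logit = log_bf + log_prior_odds
                p1 = 1.0 / (1.0 + np.exp(-logit)) if logit < 35.0 else 1.0
                delta[j] = 1.0 if np.random.random() < p1 else 0.0
            if pi == 0.0 or delta[j] == 1.0:
                c = v + sigma_e / sigma2[j]
                mean = rhs / c
                beta[j] = mean + np.random.standard_normal() * np.sqrt(sigma_e / c)
            else:
                beta[j] = 0.0
            if beta[j] != old:
                e += W[:, j] * (old - beta[j])
        # intercept
        mu_new = mu + e.mean() + np.random.standard_normal() * np.sqrt(sigma_e / n)
        e -= mu_new - mu
        mu = mu_new
        # residual variance
        sse = np.dot(e, e)
        df_e = n + nu_e
        sigma_e = (sse + nu_e * S_e) / np.random.chisquare(df_e)
        if not np.isfinite(sigma_e):
            raise RuntimeError("divergent chain")
        if it >= burnin and (it - burnin) % thin == 0:
            n_keep += 1
            beta_sum += beta
            delta_sum += delta
            mu_sum += mu
            se_sum += sigma_e
    return beta_sum / n_keep, delta_sum / n_keep, mu_sum / n_keep, se_sum / n_keep


class BayesMarkerRegression(RegressorMixin, BaseEstimator):
    """Gibbs-sampled whole-genome regression (BayesA / BayesB).

    ``pi`` is the prior probability that a marker has a zero effect: 0 gives
    BayesA, 0.95 the BayesB variant used for panel prediction.  Per-marker
    effect variances carry a scaled inverse chi-square prior with ``nu``
    degrees of freedom and scale ``scale`` (default: scale set so the prior
    mean total marker variance is half the phenotypic variance, spread over
    sum 2 p_j (1 - p_j) and the non-zero fraction 1 - pi).
    """

    def __init__(
        self,
        pi: float = 0.0,
        n_iter: int = 10000,
        burnin: int = 2000,
        thin: int = 5,
        nu: float = 4.2,
        scale: float | None = None,
        nu_e: float = 4.0,
        scale_e: float | None = None,
        random_state: int = 0,
    ):
        self.pi = pi
        self.n_iter = n_iter
        self.burnin = burnin
        self.thin = thin
        self.nu = nu
        self.scale = scale
        self.nu_e = nu_e
        self.scale_e = scale_e
        self.random_state = random_state

    def fit(self, X, y):
        if not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must be in [0, 1)")
        if min(self.n_iter, self.burnin, self.thin) <= 0 or self.burnin >= self.n_iter:
            raise ValueError("invalid chain settings")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.center_ = X.mean(axis=0)
        W = X - self.center_
        wtw = np.sum(W**2, axis=0)
        var_y = float(np.var(y))
        freqs = X.mean(axis=0) / 2.0
        sum2pq = float(np.sum(2.0 * freqs * (1.0 - freqs)))
        if self.scale is None:
            target = 0.5 * var_y / max(sum2pq, 1e-12) / (1.0 - self.pi)
            S = target * (self.nu - 2.0) / self.nu
        else:
            S = float(self.scale)
        S_e = (
            0.5 * max(var_y, 1e-12) * (self.nu_e - 2.0) / self.nu_e
            if self.scale_e is None
            else float(self.scale_e)
        )
        seed = int(self.random_state) % (2**31 - 1)
        beta, incl, mu, var_e = _gibbs_core(
            np.asfortranarray(W),
            y,
            wtw,
            float(self.pi),
            int(self.n_iter),
            int(self.burnin),
            int(self.thin),
            float(self.nu),
            float(max(S, 1e-12)),
            float(self.nu_e),
            float(S_e),
            seed,
        )
        self.coef_ = beta
        self.inclusion_ = incl
        self.mu_ = float(mu)
        self.var_e_ = float(var_e)
        self.intercept_ = self.mu_ - self.center_ @ self.coef_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


# --------------------------------------------------------------------------
# LASSO by cyclic coordinate descent
# --------------------------------------------------------------------------


@njit(cache=True)
def _cd_sweep(W, r, beta, wtw_n, t, n, active_only):
    max_delta = 0.0
    for j in range(W.shape[1]):
        if wtw_n[j] <= 0.0 or (active_only and beta[j] == 0.0):
            continue
        z = np.dot(W[:, j], r) / n + wtw_n[j] * beta[j]
        if z > t:
            new = (z - t) / wtw_n[j]
        elif z < -t:
            new = (z + t) / wtw_n[j]
        else:
            new = 0.0
        d = new - beta[j]
        if d != 0.0:
            r -= W[:, j] * d
            beta[j] = new
            if abs(d) > max_delta:
                max_delta = abs(d)
    return max_delta


@njit(cache=True)
def _lasso_path_core(W, y, wtw_n, grid, tol, max_sweeps):
    # active-set cyclic coordinate descent with warm starts along the grid
    n, p = W.shape
    betas = np.zeros((len(grid), p))
    beta = np.zeros(p)
    r = y.copy()
    for gi in range(len(grid)):
        t = grid[gi]
        sweeps = 0
        while True:
            sweeps += 1
            if sweeps > max_sweeps:
                raise RuntimeError("coordinate descent did not converge")
            d_full = _cd_sweep(W, r, beta, wtw_n, t, n, False)
            if d_full < tol:
                break
            while True:
                sweeps += 1
                if sweeps > max_sweeps:
                    raise RuntimeError("coordinate descent did not converge")
                if _cd_sweep(W, r, beta, wtw_n, t, n, True) < tol:
                    break
        betas[gi] = beta
    return betas


class MarkerLasso(RegressorMixin, BaseEstimator):
    """L1-penalized marker regression, objective (1/2n)||y-mu-Wb||^2 + t||b||_1.

    The penalty ``t`` is tuned by ``cv_folds``-fold cross-validation over a
    decreasing log-spaced grid from t_max (smallest penalty with an all-zero
    solution) unless given explicitly.  Warm starts along the grid make the
    whole path cheap.  Exact MSEP ties resolve to the larger penalty.
    """

    def __init__(
        self,
        t: float | None = None,
        n_grid: int = 100,
        grid_ratio: float = 1e-3,
        cv_folds: int = 10,
        tol: float = 1e-7,
        max_sweeps: int = 100_000,
        random_state: int = 0,
    ):
        self.t = t
        self.n_grid = n_grid
        self.grid_ratio = grid_ratio
        self.cv_folds = cv_folds
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.random_state = random_state

    def _path(self, W, yc, grid):
        wtw_n = np.sum(W**2, axis=0) / len(yc)
        return _lasso_path_core(
            np.asfortranarray(W), yc.copy(), wtw_n, grid, self.tol, self.max_sweeps
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        self.center_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        W = X - self.center_
        yc = y - self.y_mean_
        t_max = float(np.max(np.abs(W.T @ yc)) / n) if p else 0.0
        if self.t is not None:
            grid = np.geomspace(max(t_max, self.t), self.t, num=20)
            t_star = float(self.t)
            tuning = None
        else:
            if t_max <= 0:
                t_star, grid, tuning = 0.0, np.array([0.0]), None
            else:
                grid = np.geomspace(t_max, t_max * self.grid_ratio, num=self.n_grid)
                lab = cv_folds(n, self.cv_folds, self.random_state)
                msep = np.zeros(len(grid))
                for f in range(self.cv_folds):
                    tr = lab != f
                    Wf = X[tr] - X[tr].mean(axis=0)
                    yf = y[tr] - y[tr].mean()
                    betas = self._path(Wf, yf, grid)
                    pred = (X[~tr] - X[tr].mean(axis=0)) @ betas.T + y[tr].mean()
                    msep += np.mean((pred - y[~tr, None]) ** 2, axis=0)
                msep /= self.cv_folds
                t_star = float(grid[int(np.argmin(msep))])  # grid descending: tie -> larger t
                tuning = TuningResult(grid=grid, msep=msep, selected=t_star)
        fit_grid = grid[grid >= t_star] if len(grid) else np.array([t_star])
        betas = self._path(W, yc, np.append(fit_grid[fit_grid > t_star], t_star))
        self.coef_ = betas[-1]
        self.t_ = t_star
        self.tuning_ = tuning
        self.mu_ = self.y_mean_
        self.intercept_ = self.y_mean_ - self.center_ @ self.coef_
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


# --------------------------------------------------------------------------
# kernel-algorithm PLS
# --------------------------------------------------------------------------


def _pls1_kernel(W, yc, k_max):
    """Univariate PLS via the kernel algorithm (deflation on K = W W').

    Returns (V, U, q, K0): n-space weight/loading surrogates and score
    regression coefficients such that for k components the marker effects
    are ``W' V_k (U_k' K0 V_k)^-1 q_k``.
    """
    n = len(yc)
    K0 = W @ W.T
    K = K0.copy()
    yk = yc.copy()
    Dt = np.eye(n)  # transpose of the accumulated deflation projector
    V = np.zeros((n, k_max))
    U = np.zeros((n, k_max))
    q = np.zeros(k_max)
    k_eff = 0
    for a in range(k_max):
        z = K @ yk
        nz = np.linalg.norm(z)
        if nz <= 1e-12 * max(1.0, np.linalg.norm(yk)):
            break
        t = z / nz
        V[:, a] = Dt @ yk / nz
        U[:, a] = Dt @ t
        q[a] = yk @ t
        proj = np.eye(n) - np.outer(t, t)
        K = proj @ K @ proj
        yk = yk - t * q[a]
        Dt = Dt @ proj
        k_eff += 1
    return V[:, :k_eff], U[:, :k_eff], q[:k_eff], K0


def _pls1_nipals(W, yc, k_max):
    """Classical NIPALS PLS1 with explicit X deflation (reference algorithm)."""
    Xa = W.copy()
    ya = yc.copy()
    Wm = np.zeros((W.shape[1], k_max))
    P = np.zeros((W.shape[1], k_max))
    q = np.zeros(k_max)
    k_eff = 0
    for a in range(k_max):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw <= 1e-12:
            break
        w /= nw
        t = Xa @ w
        tt = t @ t
        if tt <= 1e-24:
            break
        P[:, a] = Xa.T @ t / tt
        q[a] = ya @ t / tt
        Xa = Xa - np.outer(t, P[:, a])
        ya = ya - t * q[a]
        Wm[:, a] = w
        k_eff += 1
    Wk, Pk, qk = Wm[:, :k_eff], P[:, :k_eff], q[:k_eff]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk) if k_eff else np.zeros(W.shape[1])


def _kernel_coefs(W, V, U, q, K0):
    """Marker-effect vectors for every component count 1..k."""
    coefs = []
    for k in range(1, V.shape[1] + 1):
        A = U[:, :k].T @ K0 @ V[:, :k]
        coefs.append(W.T @ (V[:, :k] @ np.linalg.solve(A, q[:k])))
    return coefs


class KernelPLS(RegressorMixin, BaseEstimator):
    """Univariate PLS regression computed with the kernel algorithm.

    The latent-component count is tuned by ``cv_folds``-fold CV minimizing
    MSEP over 1..``k_max`` unless ``n_components`` is given; exact ties go
    to the smaller count.
    """

    def __init__(
        self,
        n_components: int | None = None,
        k_max: int = 30,
        cv_folds: int = 10,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.k_max = k_max
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if np.var(y) == 0:
            raise ValueError("zero-variance response")
        k_cap = min(self.k_max, n - 1, p)
        self.center_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        if self.n_components is not None:
            if self.n_components > k_cap:
                raise ValueError(f"n_components > min(n-1, p) = {k_cap}")
            k_star, tuning = int(self.n_components), None
        else:
            lab = cv_folds(n, self.cv_folds, self.random_state)
            msep = np.zeros(k_cap)
            counts = np.zeros(k_cap)
            for f in range(self.cv_folds):
                tr = lab != f
                kf = min(k_cap, tr.sum() - 1)
                Wf = X[tr] - X[tr].mean(axis=0)
                yf = y[tr] - y[tr].mean()
                coefs = _kernel_coefs(Wf, *_pls1_kernel(Wf, yf, kf))
                Wte = X[~tr] - X[tr].mean(axis=0)
                for k, b in enumerate(coefs):
                    pred = Wte @ b + y[tr].mean()
                    msep[k] += np.mean((pred - y[~tr]) ** 2)
                    counts[k] += 1
            ok = counts > 0
            msep[ok] /= counts[ok]
            msep[~ok] = np.inf
            k_star = int(np.argmin(msep)) + 1  # ties -> smaller k
            tuning = TuningResult(
                grid=np.arange(1, k_cap + 1), msep=msep, selected=k_star
            )
        W = X - self.center_
        yc = y - self.y_mean_
        V, U, q, K0 = _pls1_kernel(W, yc, k_star)
        coefs = _kernel_coefs(W, V, U, q, K0)
        self.coef_ = coefs[-1] if coefs else np.zeros(p)
        self.n_components_ = len(coefs)
        self.tuning_ = tuning
        self.mu_ = self.y_mean_
        self.intercept_ = self.y_mean_ - self.center_ @ self.coef_
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


# --------------------------------------------------------------------------
# GenotypeMatrix-level surface
# --------------------------------------------------------------------------


@dataclass
class FittedModel:
    """A fitted predictor bound to the marker ids it was trained on."""

    method: str
    estimator: BaseEstimator
    marker_ids: np.ndarray

    @property
    def intercept(self) -> float:
        return float(self.estimator.intercept_)

    @property
    def effects(self) -> np.ndarray:
        return self.estimator.coef_

    @property
    def tuning(self):
        return getattr(self.estimator, "tuning_", None)


def make_model(method: str, seed: int = 0, **overrides) -> BaseEstimator:
    """Estimator factory for the five method tags used across experiments."""
    method = method.lower()
    if method == "gblup":
        return GBLUP(**overrides)
    if method == "bayesa":
        return BayesMarkerRegression(pi=0.0, random_state=seed, **overrides)
    if method == "bayesb":
        return BayesMarkerRegression(pi=0.95, random_state=seed, **overrides)
    if method == "lasso":
        return MarkerLasso(random_state=seed, **overrides)
    if method == "kplsr":
        return KernelPLS(random_state=seed, **overrides)
    raise ValueError(f"unknown method {method!r}")


def _fit_wrapper(method, y, gm_train: GenotypeMatrix, estimator) -> FittedModel:
    gm_train.require_complete("model fitting")
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    estimator.fit(gm_train.codes.astype(float), y)
    return FittedModel(method=method, estimator=estimator, marker_ids=gm_train.markers)


def fit_gblup(
    y, gm_train: GenotypeMatrix, G: RelationshipMatrix | None = None, ratio=None
) -> FittedModel:
    gm_train.require_complete("model fitting")
    est = GBLUP(ratio=ratio)
    Gmat = None
    if G is not None:
        Gmat = G.subset(gm_train.individuals).values
    est.fit(gm_train.codes.astype(float), np.asarray(y, dtype=float), G=Gmat)
    return FittedModel(method="gblup", estimator=est, marker_ids=gm_train.markers)


def fit_bayes(y, gm_train: GenotypeMatrix, pi: float = 0.0, seed: int = 0, **chain) -> FittedModel:
    est = BayesMarkerRegression(pi=pi, random_state=seed, **chain)
    tag = "bayesb" if pi > 0 else "bayesa"
    return _fit_wrapper(tag, y, gm_train, est)


def fit_lasso(y, gm_train: GenotypeMatrix, grid=None, seed: int = 0) -> FittedModel:
    est = MarkerLasso(random_state=seed)
    return _fit_wrapper("lasso", y, gm_train, est)


def fit_kplsr(y, gm_train: GenotypeMatrix, k_max: int = 30, seed: int = 0) -> FittedModel:
    est = KernelPLS(k_max=k_max, random_state=seed)
    return _fit_wrapper("kplsr", y, gm_train, est)


def predict_gebv(model: FittedModel, gm_test: GenotypeMatrix) -> np.ndarray:
    """GEBVs for a genotyped test set; test markers must cover the model's."""
    gm_test.require_complete("prediction")
    missing = set(model.marker_ids) - set(gm_test.markers)
    if missing:
        raise KeyError(f"test set lacks model markers: {sorted(missing)[:5]}")
    sub = gm_test.select_markers(model.marker_ids)
    return model.estimator.predict(sub.codes.astype(float))
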