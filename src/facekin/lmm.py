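"""Random-intercept linear mixed model with Satterthwaite F tests.

The univariate analyses need a repeated-measures model of the form

    y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)

with subject i as the only random effect (a random intercept), fitted by
maximum likelihood or REML, and type III F tests whose denominator
degrees of freedom come from the Satterthwaite approximation. No
installed Python library exposes Satterthwaite df for mixed models, and
the approximation needs the curvature of the profile likelihood in the
variance parameters, so the whole model is implemented here on the
closed-form profile likelihood of the two variance components. The fit
is cross-checked against statsmodels' MixedLM and against lme4/lmerTest
in the test suite.

For the compound-symmetry structure the marginal covariance of each
subject block is ``sigma^2 I + tau^2 J``, whose inverse and determinant
are available in closed form (Sherman-Morrison), so every likelihood
evaluation is O(n_groups * p^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateModelError

__all__ = ["RandomInterceptLMM", "fit_random_intercept", "satterthwaite_F"]


@dataclass
class _GroupStats:
    """Per-group sufficient statistics for the profile likelihood."""

    n: np.ndarray          # (g,) group sizes
    XtX: np.ndarray        # (g, p, p)
    Xt1: np.ndarray        # (g, p)  X_i' 1
    Xty: np.ndarray        # (g, p)
    s: np.ndarray          # (g,)  1' y_i
    yy: np.ndarray         # (g,)  y_i' y_i


def _group_stats(X: np.ndarray, y: np.ndarray, codes: np.ndarray) -> _GroupStats:
    g = codes.max() + 1
    p = X.shape[1]
    XtX = np.zeros((g, p, p))
    Xt1 = np.zeros((g, p))
    Xty = np.zeros((g, p))
    s = np.zeros(g)
    yy = np.zeros(g)
    n = np.bincount(codes, minlength=g).astype(float)
    for i in range(g):
        Xi = X[codes == i]
        yi = y[codes == i]
        XtX[i] = Xi.T @ Xi
        Xt1[i] = Xi.sum(axis=0)
        Xty[i] = Xi.T @ yi
        s[i] = yi.sum()
        yy[i] = yi @ yi
    return _GroupStats(n, XtX, Xt1, Xty, s, yy)


def _gls_pieces(gs: _GroupStats, sigma2: float, tau2: float):
    """A = X'V^-1 X, b = X'V^-1 y, yVy = y'V^-1 y, logdetV for given variances."""
    c = tau2 / (sigma2 + gs.n * tau2)                      # (g,)
    A = (gs.XtX.sum(axis=0)
         - np.einsum("g,gp,gq->pq", c, gs.Xt1, gs.Xt1)) / sigma2
    b = (gs.Xty.sum(axis=0) - (c * gs.s) @ gs.Xt1) / sigma2
    yVy = (gs.yy.sum() - np.sum(c * gs.s ** 2)) / sigma2
    logdetV = float(np.sum((gs.n - 1) * np.log(sigma2)
                           + np.log(sigma2 + gs.n * tau2)))
    return A, b, yVy, logdetV


def _profile_nll(log_theta: np.ndarray, gs: _GroupStats, n: int, p: int,
                 reml: bool) -> float:
    sigma2, tau2 = np.exp(log_theta)
    A, b, yVy, logdetV = _gls_pieces(gs, sigma2, tau2)
    try:
        cho = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(A, b)
    rss = yVy - b @ beta
    nll = 0.5 * (n * np.log(2 * np.pi) + logdetV + rss)
    if reml:
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cho))))
        nll += 0.5 * (logdetA - p * np.log(2 * np.pi))
    return float(nll)


@dataclass
class RandomInterceptLMM:
    """A fitted random-intercept mixed model.

    Attributes
    ----------
    beta, cov_beta : GLS fixed-effect estimates and their covariance
        ``(X'V^-1 X)^-1`` at the estimated variances.
    sigma2, tau2 : residual and random-intercept variance estimates.
    theta_cov : 2x2 asymptotic covariance of (sigma2, tau2) from the
        observed information of the profile (restricted) likelihood.
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    theta_cov: np.ndarray
    loglik: float
    reml: bool
    n_obs: int
    n_groups: int
    X: np.ndarray
    _gs: _GroupStats

    def cov_beta_at(self, sigma2: float, tau2: float) -> np.ndarray:
        A, _, _, _ = _gls_pieces(self._gs, sigma2, tau2)
        return np.linalg.inv(A)

    @property
    def fitted_fixed(self) -> np.ndarray:
        return self.X @ self.beta

    def r_squared(self) -> tuple[float, float]:
        """Variance-decomposition (marginal, conditional) R^2.

        Marginal: variance of the fixed-effect predictions over total
        (fixed + intercept + residual) variance; conditional adds the
        random-intercept variance to the numerator.
        """
        var_f = float(np.var(self.fitted_fixed))
        total = var_f + self.tau2 + self.sigma2
        return var_f / total, (var_f + self.tau2) / total


def fit_random_intercept(X: np.ndarray, y: np.ndarray, groups,
                         reml: bool = False) -> RandomInterceptLMM:
    """Fit ``y = X beta + u_group + e`` by (restricted) maximum likelihood.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) response.
    groups : length-n labels of the grouping factor (subjects).
    reml : use REML instead of ML. ML matches software that reports
        type III tables from ML fits; REML reproduces the classical
        balanced-design ANOVA exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.ptp(y) == 0:
        raise DegenerateModelError("response has zero variance")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the aliased columns via QR pivoting
        _, R, piv = _pivoted_qr(X)
        aliased = sorted(piv[rank:].tolist())
        raise DegenerateModelError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"aliased columns {aliased}"
        )
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    if codes.max() + 1 < 2:
        raise DegenerateModelError("need at least 2 groups")
    gs = _group_stats(X, y, codes)

    # Moment-based initialization from the OLS fit.
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    v = float(resid @ resid / max(n - p, 1))
    gmeans = np.bincount(codes, weights=resid) / gs.n
    tau0 = max(float(np.var(gmeans)), v * 1e-3)
    x0 = np.log([max(v, 1e-12), tau0])

    res = optimize.minimize(
        _profile_nll, x0, args=(gs, n, p, reml), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
    )
    sigma2, tau2 = np.exp(res.x)

    A, b, _, _ = _gls_pieces(gs, sigma2, tau2)
    cov_beta = np.linalg.inv(A)
    beta = cov_beta @ b

    theta_cov = _observed_info_inv(gs, n, p, reml, sigma2, tau2)
    return RandomInterceptLMM(
        beta=beta, cov_beta=cov_beta, sigma2=float(sigma2), tau2=float(tau2),
        theta_cov=theta_cov, loglik=-float(res.fun), reml=reml,
        n_obs=n, n_groups=int(codes.max()) + 1, X=X, _gs=gs,
    )


def _pivoted_qr(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, pivoting=True, mode="economic")
    return Q, R, piv


def _observed_info_inv(gs: _GroupStats, n: int, p: int, reml: bool,
                       sigma2: float, tau2: float) -> np.ndarray:
    """Inverse Hessian of the profile NLL w.r.t. (sigma2, tau2) by central
    differences on the variance scale."""

    def f(theta):
        return _profile_nll(np.log(np.maximum(theta, 1e-300)), gs, n, p, reml)

    theta = np.array([sigma2, tau2], dtype=float)
    h = np.maximum(1e-5 * np.abs(theta), 1e-10 * sigma2)
    H = np.zeros((2, 2))
    f0 = f(theta)
    for i in range(2):
        ei = np.zeros(2); ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
    ei = np.array([h[0], 0.0]); ej = np.array([0.0, h[1]])
    H[0, 1] = H[1, 0] = (
        f(theta + ei + ej) - f(theta + ei - ej)
        - f(theta - ei + ej) + f(theta - ei - ej)
    ) / (4 * h[0] * h[1])
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def satterthwaite_F(fit: RandomInterceptLMM, L: np.ndarray
                    ) -> tuple[float, float, float, float]:
    """Type III F test of the multi-row contrast ``L beta = 0``.

    Returns ``(F, num_df, den_df, p)``. The denominator df follow the
    Satterthwaite approach for mixed models: the contrast covariance
    ``L C(theta) L'`` is eigendecomposed, each 1-df component gets
    ``nu_m = 2 f_m^2 / Var(f_m)`` with ``Var(f_m)`` from the delta method
    through the asymptotic covariance of the variance estimates, and the
    components are pooled into a single denominator df.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = L.shape[0]
    M = L @ fit.cov_beta @ L.T
    Lb = L @ fit.beta
    F = float(Lb @ np.linalg.solve(M, Lb)) / q

    evals, P = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, P = evals[order], P[:, order]

    theta = np.array([fit.sigma2, fit.tau2])
    h = np.maximum(1e-5 * np.abs(theta), 1e-10 * fit.sigma2)
    # gradient of each eigen-contrast variance w.r.t. (sigma2, tau2)
    grads = np.zeros((q, 2))
    for k in range(2):
        tp = theta.copy(); tp[k] += h[k]
        tm = theta.copy(); tm[k] -= h[k]
        Cp = fit.cov_beta_at(*tp)
        Cm = fit.cov_beta_at(*tm)
        for m in range(q):
            lm = L.T @ P[:, m]
            grads[m, k] = (lm @ Cp @ lm - lm @ Cm @ lm) / (2 * h[k])

    nu = np.full(q, np.inf)
    for m in range(q):
        var_fm = float(grads[m] @ fit.theta_cov @ grads[m])
        if var_fm > 0:
            nu[m] = 2.0 * evals[m] ** 2 / var_fm
    usable = nu[nu > 2]
    if usable.size == 0:
        den_df = float(fit.n_obs - fit.X.shape[1])
    else:
        E = float(np.sum(usable / (usable - 2)))
        den_df = 2.0 * E / (E - q) if E > q else float(fit.n_obs)
    p_val = float(stats.f.sf(F, q, den_df))
    return F, float(q), float(den_df), p_val
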