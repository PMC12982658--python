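"""Gamma random-intercept mixed model with log link.

Skin-conductance amplitudes and (transformed) EMG durations are positive and
right-skewed, so condition effects are modelled on the log scale of a Gamma
response with a per-subject random intercept:

    y_ij | b_i ~ Gamma(shape k, mean mu_ij),   log mu_ij = x_ij' beta + b_i,
    b_i ~ N(0, sigma_b^2).

The marginal likelihood integrates the random intercept out by adaptive
Gauss-Hermite quadrature: for each subject the conditional posterior mode of
b_i is located by Newton's method (the conditional log-density is strictly
concave in b_i), the quadrature grid is centered and scaled there, and the
log-sum-exp of the node contributions gives the subject's marginal
log-likelihood.  The fixed effects, log shape and log random-intercept SD
are then maximized jointly with L-BFGS-B; standard errors come from the
numerical Hessian of the negative marginal log-likelihood at the optimum.

With the default 15 quadrature nodes the fit reproduces glmmTMB's Gamma
log-link estimates to several decimal places (see the test suite), while a
single node recovers the plain Laplace approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import stats as spstats
from scipy.optimize import minimize
from scipy.special import gammaln
from statsmodels.tools.numdiff import approx_hess

__all__ = ["GammaGLMMResult", "fit_gamma_glmm"]


@dataclass
class GammaGLMMResult:
    """Maximum-likelihood fit of the Gamma log-link random-intercept model."""

    params: np.ndarray            # fixed effects, log-mean scale
    bse: np.ndarray               # their standard errors
    cov_params: np.ndarray        # fixed-effect covariance block
    exog_names: list[str]
    shape: float                  # Gamma shape k (inverse squared CV)
    sigma_b: float                # random-intercept SD
    loglik: float
    nobs: int
    df_resid: int
    converged: bool

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * spstats.t.sf(np.abs(self.tvalues), self.df_resid)

    def contrast(self, c: np.ndarray) -> dict:
        """Estimate, SE, t, residual df and p for the linear combination c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov_params @ c))
        t = est / se
        p = 2 * float(spstats.t.sf(abs(t), self.df_resid))
        return {"estimate": est, "se": se, "t": t, "df": self.df_resid, "p": p}

    def wald_f(self, L: np.ndarray) -> dict:
        """Wald F-test of L beta = 0 with residual denominator df."""
        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = L.shape[0]
        est = L @ self.params
        V = L @ self.cov_params @ L.T
        F = float(est @ np.linalg.solve(V, est)) / q
        p = float(spstats.f.sf(F, q, self.df_resid))
        return {"F": F, "df1": q, "df2": self.df_resid, "p": p}


class _MarginalNLL:
    """Negative marginal log-likelihood with warm-started posterior modes."""

    def __init__(self, y, X, groups, n_nodes):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        uniq, inv = np.unique(np.asarray(groups), return_inverse=True)
        self.sub = inv
        self.n_sub = uniq.size
        self.nodes, self.wts = hermgauss(n_nodes)
        self.logy = np.log(self.y)
        self.b = np.zeros(self.n_sub)
        self.n_per = np.bincount(self.sub, minlength=self.n_sub).astype(float)

    def __call__(self, theta: np.ndarray) -> float:
        y, X, sub, n_sub = self.y, self.X, self.sub, self.n_sub
        p = X.shape[1]
        beta = theta[:p]
        k = np.exp(theta[p])
        sig2 = np.exp(2.0 * theta[p + 1])
        eta0 = X @ beta
        b = self.b.copy()
        # Newton iterations for the conditional modes (strictly concave in b)
        for _ in range(50):
            w = k * y * np.exp(-(eta0 + b[sub]))
            sw = np.bincount(sub, w, n_sub)
            g1 = sw - k * self.n_per - b / sig2
            g2 = -sw - 1.0 / sig2
            step = g1 / g2
            b -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        self.b = b
        w = k * y * np.exp(-(eta0 + b[sub]))
        g2 = -np.bincount(sub, w, n_sub) - 1.0 / sig2
        s = 1.0 / np.sqrt(-g2)
        # adaptive Gauss-Hermite around (b, s)
        bm = b[:, None] + np.sqrt(2.0) * s[:, None] * self.nodes[None, :]
        etam = eta0[:, None] + bm[sub]
        lp = (
            k * (np.log(k) - etam)
            + (k - 1.0) * self.logy[:, None]
            - k * y[:, None] * np.exp(-etam)
            - gammaln(k)
        )
        lsum = np.zeros((n_sub, self.nodes.size))
        np.add.at(lsum, sub, lp)
        acc = (
            np.log(self.wts)[None, :]
            + self.nodes[None, :] ** 2
            + lsum
            - 0.5 * np.log(2.0 * np.pi * sig2)
            - bm**2 / (2.0 * sig2)
        )
        m = acc.max(axis=1)
        ll = m + np.log(np.exp(acc - m[:, None]).sum(axis=1)) + np.log(np.sqrt(2.0) * s)
        return -float(ll.sum())


def fit_gamma_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    exog_names: list[str] | None = None,
    n_nodes: int = 15,
    start_sigma_b: float = 0.3,
) -> GammaGLMMResult:
    """Fit the Gamma log-link random-intercept model by adaptive quadrature.

    Parameters
    ----------
    y : strictly positive responses.
    X : fixed-effect design matrix (include the intercept column).
    groups : subject identifier per row.
    n_nodes : Gauss-Hermite nodes; 1 gives the Laplace approximation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y <= 0):
        raise ValueError(
            "Gamma log-link model requires strictly positive responses; "
            "transform or exclude non-positive values first"
        )
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per observation")
    exog_names = exog_names or [f"x{j}" for j in range(X.shape[1])]

    # moment start from a pooled Gamma GLM
    import statsmodels.api as sm

    glm = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit()
    k0 = max(1.0 / glm.scale, 1e-3)
    x0 = np.r_[glm.params, np.log(k0), np.log(start_sigma_b)]

    nll = _MarginalNLL(y, X, groups, n_nodes)
    res = minimize(nll, x0, method="L-BFGS-B", options=dict(ftol=1e-12, gtol=1e-7, maxiter=500))

    p = X.shape[1]
    H = approx_hess(res.x, nll)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    cov_fe = cov_all[:p, :p]
    bse = np.sqrt(np.maximum(np.diag(cov_fe), 0.0))
    return GammaGLMMResult(
        params=res.x[:p],
        bse=bse,
        cov_params=cov_fe,
        exog_names=list(exog_names),
        shape=float(np.exp(res.x[p])),
        sigma_b=float(np.exp(res.x[p + 1])),
        loglik=-float(res.fun),
        nobs=int(y.size),
        df_resid=int(y.size - p),
        converged=bool(res.success),
    )
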