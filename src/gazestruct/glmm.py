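"""Maximum-likelihood GLMMs with crossed random intercepts.

Binomial-logit and Poisson-log mixed models estimated by the Laplace
approximation: for candidate variance parameters, the joint mode of
(fixed effects, random effects) is found by penalized IRLS, and the
marginal log-likelihood is approximated as

    l(y | eta_hat) - u_hat' Sigma^-1 u_hat / 2 - log det(Sigma Z'WZ + I) / 2.

The outer optimizer runs over the log random-intercept SDs (Nelder-Mead;
at most a handful of grouping factors).  Fixed effects are profiled inside
the penalized IRLS, the approach used by fast GLMM implementations.  Wald
standard errors come from the fixed-effect block of the inverse penalized
Fisher information at the optimum.

This estimator exists because the analysis needs ML log-likelihoods for
chi-square likelihood-ratio tests on nested binomial mixed models, which
the available Gaussian mixed-model backends do not provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = ["GlmmFit", "fit_glmm"]

_MAX_ABS_COEF = 15.0  # beyond this on the logit scale, treat as separation


@dataclass
class GlmmFit:
    """Fitted mixed model; coefficients on the linear-predictor scale."""

    params: np.ndarray
    bse: np.ndarray
    term_names: list[str]
    re_sd: dict[str, float]
    loglik: float
    family: str
    n: int
    converged: bool
    message: str = ""
    ranef: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ci(self) -> np.ndarray:
        lo = self.params - 1.96 * self.bse
        hi = self.params + 1.96 * self.bse
        return np.column_stack([lo, hi])

    @property
    def n_params(self) -> int:
        return len(self.params) + len(self.re_sd)


def _family_funcs(family: str):
    if family == "binomial":
        def mu_f(eta):
            return special.expit(eta)

        def w_f(mu):
            return np.clip(mu * (1 - mu), 1e-10, None)

        def ll_f(y, mu):
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

    elif family == "poisson":
        def mu_f(eta):
            return np.exp(np.clip(eta, -30, 30))

        def w_f(mu):
            return np.clip(mu, 1e-10, None)

        def ll_f(y, mu):
            mu = np.clip(mu, 1e-12, None)
            return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))

    else:
        raise ValueError(f"unknown family {family!r}")
    return mu_f, w_f, ll_f


def _design(groups: dict[str, np.ndarray], n: int):
    """Indicator matrix Z and per-factor column slices."""
    blocks, slices, levels = [], {}, {}
    start = 0
    for name, codes in groups.items():
        codes = np.asarray(codes)
        uniq, idx = np.unique(codes, return_inverse=True)
        q = len(uniq)
        Zg = np.zeros((n, q))
        Zg[np.arange(n), idx] = 1.0
        blocks.append(Zg)
        slices[name] = slice(start, start + q)
        levels[name] = uniq
        start += q
    Z = np.hstack(blocks) if blocks else np.zeros((n, 0))
    return Z, slices, levels


def _pirls(y, X, Z, prec_diag, family, max_iter=100, tol=1e-8):
    """Penalized IRLS over (beta, u); penalty only on u."""
    mu_f, w_f, ll_f = _family_funcs(family)
    n, p = X.shape
    q = Z.shape[1]
    A = np.hstack([X, Z])
    P = np.zeros(p + q)
    P[p:] = prec_diag
    gamma = np.zeros(p + q)
    if family == "binomial":
        gamma[0] = special.logit(np.clip(y.mean(), 1e-3, 1 - 1e-3)) if X[:, 0].std() == 0 else 0.0
    obj_prev = -np.inf
    for _ in range(max_iter):
        eta = A @ gamma
        mu = mu_f(eta)
        w = w_f(mu)
        z = eta + (y - mu) / w
        AtW = A.T * w
        H = AtW @ A
        H[np.arange(p + q), np.arange(p + q)] += P
        rhs = AtW @ z
        try:
            gamma_new = np.linalg.solve(H, rhs)
        except np.linalg.LinAlgError:
            return gamma, H, False
        # step-halving on the penalized objective
        for _h in range(8):
            eta_n = A @ gamma_new
            obj = ll_f(y, mu_f(eta_n)) - 0.5 * float(np.sum(P * gamma_new**2))
            if obj >= obj_prev - 1e-10 or not np.isfinite(obj_prev):
                break
            gamma_new = 0.5 * (gamma_new + gamma)
        delta = np.max(np.abs(gamma_new - gamma))
        gamma = gamma_new
        if np.isfinite(obj) and abs(obj - obj_prev) < tol and delta < 1e-6:
            obj_prev = obj
            break
        obj_prev = obj
    eta = A @ gamma
    mu = mu_f(eta)
    w = w_f(mu)
    AtW = A.T * w
    H = AtW @ A
    H[np.arange(p + q), np.arange(p + q)] += P
    return gamma, H, True


def _laplace_loglik(y, X, Z, slices, sigmas, family):
    mu_f, w_f, ll_f = _family_funcs(family)
    n, p = X.shape
    q = Z.shape[1]
    prec = np.zeros(q)
    for name, sl in slices.items():
        prec[sl] = 1.0 / max(sigmas[name] ** 2, 1e-12)
    gamma, H, ok = _pirls(y, X, Z, prec, family)
    if not ok:
        return -np.inf, gamma, H
    beta, u = gamma[:p], gamma[p:]
    eta = X @ beta + Z @ u
    mu = mu_f(eta)
    ll_cond = ll_f(y, mu)
    pen = 0.5 * float(np.sum(prec * u**2))
    w = w_f(mu)
    # log det(Sigma Z'WZ + I) via the u-block of the penalized Hessian:
    # H_uu = Z'WZ + Sigma^-1, so det(Sigma Z'WZ + I) = det(H_uu) * det(Sigma)
    Huu = (Z.T * w) @ Z
    Huu[np.arange(q), np.arange(q)] += prec
    sign, logdet_H = np.linalg.slogdet(Huu)
    if sign <= 0:
        return -np.inf, gamma, H
    logdet_sigma = -float(np.sum(np.log(prec)))
    llap = ll_cond - pen - 0.5 * (logdet_H + logdet_sigma)
    return llap, gamma, H


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    term_names: list[str],
    groups: dict[str, np.ndarray],
    family: str = "binomial",
) -> GlmmFit:
    """Fit a GLMM with crossed random intercepts by Laplace-approximate ML.

    Parameters
    ----------
    y, X
        Response and fixed-effect design matrix (include the intercept
        column explicitly).
    groups
        Mapping from grouping-factor name to a length-n code array; each
        factor contributes an independent random intercept per level.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if family == "binomial" and (y.min() == y.max()):
        raise ValueError(
            "response is constant: complete separation, the binomial GLMM is not identified"
        )
    Z, slices, levels = _design(groups, n)
    names = list(groups)

    if not names:
        llap, gamma, H = _laplace_loglik(y, X, Z, {}, {}, family)
        cov = np.linalg.inv(H)
        return GlmmFit(gamma[:p], np.sqrt(np.diag(cov)[:p]), term_names, {}, llap, family, n, True)

    def neg(log_sig):
        sigmas = {nm: float(np.exp(s)) for nm, s in zip(names, log_sig)}
        llap, _, _ = _laplace_loglik(y, X, Z, slices, sigmas, family)
        return -llap if np.isfinite(llap) else 1e12

    x0 = np.full(len(names), np.log(0.5))
    res = optimize.minimize(
        neg, x0, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400 * len(names)},
    )
    sigmas = {nm: float(np.exp(s)) for nm, s in zip(names, res.x)}
    llap, gamma, H = _laplace_loglik(y, X, Z, slices, sigmas, family)
    beta = gamma[:p]
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)

    converged = bool(res.success) and np.isfinite(llap)
    message = "" if converged else f"outer optimizer: {res.message}"
    if np.max(np.abs(beta)) > _MAX_ABS_COEF and family == "binomial":
        converged = False
        message = "coefficients diverged: possible complete separation"
    ranef = {nm: gamma[p:][slices[nm]] for nm in names}
    return GlmmFit(
        params=beta,
        bse=bse,
        term_names=term_names,
        re_sd=sigmas,
        loglik=float(llap),
        family=family,
        n=n,
        converged=converged,
        message=message,
        ranef=ranef,
    )
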