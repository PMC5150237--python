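"""Binomial (logit) mixed models with crossed Gaussian random intercepts.

Maximum-likelihood fitting under the Laplace approximation, in the
spherical parameterization ``u_f = sigma_f * v_f`` with ``v ~ N(0, I)``:
an inner penalized IRLS profiles the fixed effects and the random-effect
modes jointly at fixed variance parameters, and an outer Nelder-Mead
optimizes the standard deviations ``sigma_f >= 0``. This is the
``nAGQ = 0``-style Laplace scheme of lme4; the approximation is used
identically for every model a likelihood-ratio test compares, and the
parametric bootstrap calibrates the resulting statistic, so no claim rests
on the absolute accuracy of the approximated likelihood.

The inner loop is numba-compiled: a parametric-bootstrap LRT refits both
models hundreds of times, and calibration studies refit them tens of
thousands of times.

-2 log L = binomial deviance + v'v + log det((Z Lambda)' W (Z Lambda) + I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import minimize

__all__ = ["MixedLogitFit", "fit_mixed_logit"]


@njit(cache=True)
def _dev_at(X, y, codes, offs, sigma, beta, v):
    n, p = X.shape
    k = offs.shape[0]
    dev = 0.0
    for i in range(n):
        e = 0.0
        for j in range(p):
            e += X[i, j] * beta[j]
        for f in range(k):
            e += sigma[f] * v[offs[f] + codes[f, i]]
        # -2 * Bernoulli log-likelihood, stable in both tails
        if e > 0.0:
            base = np.log1p(np.exp(-e))
            dev += 2.0 * (base if y[i] == 1.0 else base + e)
        else:
            base = np.log1p(np.exp(e))
            dev += 2.0 * (base - e if y[i] == 1.0 else base)
    return dev


@njit(cache=True)
def _pirls(X, y, codes, offs, qs, sigma, beta, v, max_iter, tol):
    """Penalized IRLS at fixed sigma; beta and v are updated in place.

    Returns (m2ll, converged) where m2ll is the Laplace -2 log-likelihood.
    """
    n, p = X.shape
    k = offs.shape[0]
    q = 0
    for f in range(k):
        q += qs[f]
    dim = q + p
    kk = k + p
    A = np.empty((dim, dim))
    rhs = np.empty(dim)
    idx = np.empty(kk, np.int64)
    val = np.empty(kk, np.float64)
    x = np.empty(dim)
    newbeta = np.empty(p)
    newv = np.empty(q)

    pen = 0.0
    for j in range(q):
        pen += v[j] * v[j]
    pdev = _dev_at(X, y, codes, offs, sigma, beta, v) + pen
    logdet = 0.0
    converged = False

    for _ in range(max_iter):
        A[:, :] = 0.0
        rhs[:] = 0.0
        for i in range(n):
            e = 0.0
            for j in range(p):
                e += X[i, j] * beta[j]
            for f in range(k):
                e += sigma[f] * v[offs[f] + codes[f, i]]
            if e > 35.0:
                e = 35.0
            elif e < -35.0:
                e = -35.0
            m = 1.0 / (1.0 + np.exp(-e))
            wi = m * (1.0 - m)
            zi = e + (y[i] - m) / wi
            for f in range(k):
                idx[f] = offs[f] + codes[f, i]
                val[f] = sigma[f]
            for j in range(p):
                idx[k + j] = q + j
                val[k + j] = X[i, j]
            for a in range(kk):
                ia = idx[a]
                va = val[a] * wi
                rhs[ia] += va * zi
                for b in range(kk):
                    A[ia, idx[b]] += va * val[b]
        for j in range(q):
            A[j, j] += 1.0
        for j in range(dim):
            A[j, j] += 1e-12
        L = np.linalg.cholesky(A)
        # leading q x q block of L factors the random-effect information
        logdet = 0.0
        for j in range(q):
            logdet += np.log(L[j, j])
        logdet *= 2.0
        # solve A x = rhs via the Cholesky factor
        for i2 in range(dim):
            s = rhs[i2]
            for j2 in range(i2):
                s -= L[i2, j2] * x[j2]
            x[i2] = s / L[i2, i2]
        for i2 in range(dim - 1, -1, -1):
            s = x[i2]
            for j2 in range(i2 + 1, dim):
                s -= L[j2, i2] * x[j2]
            x[i2] = s / L[i2, i2]
        # step-halving line search on the penalized deviance
        step = 1.0
        accepted = False
        cand = pdev
        for _h in range(18):
            for j in range(q):
                newv[j] = v[j] + step * (x[j] - v[j])
            for j in range(p):
                newbeta[j] = beta[j] + step * (x[q + j] - beta[j])
            pen = 0.0
            for j in range(q):
                pen += newv[j] * newv[j]
            cand = _dev_at(X, y, codes, offs, sigma, newbeta, newv) + pen
            if cand <= pdev + 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        drop = pdev - cand
        for j in range(q):
            v[j] = newv[j]
        for j in range(p):
            beta[j] = newbeta[j]
        pdev = cand
        if drop < tol * (abs(pdev) + 1.0):
            converged = True
            break
    return pdev + logdet, converged


def _assemble_information(X, y, codes, offs, qs, sigma, beta, v):
    """Dense (q+p) observed-information-style matrix at the given params
    (numpy mirror of the kernel's system; used for standard errors)."""
    n, p = X.shape
    k = len(qs)
    q = int(np.sum(qs))
    eta = X @ beta
    for f in range(k):
        eta = eta + sigma[f] * v[offs[f] + codes[f]]
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = mu * (1.0 - mu)
    dim = q + p
    M = np.zeros((n, dim))
    for f in range(k):
        M[np.arange(n), offs[f] + codes[f]] = sigma[f]
    M[:, q:] = X
    A = M.T @ (M * w[:, None])
    A[np.arange(q), np.arange(q)] += 1.0
    return A


@dataclass
class MixedLogitFit:
    beta: np.ndarray
    beta_names: list[str]
    beta_se: np.ndarray
    sigma: np.ndarray
    factor_names: list[str]
    loglik: float
    m2ll: float
    converged: bool
    n_obs: int
    n_levels: np.ndarray
    u: dict[str, np.ndarray]  # BLUP-style conditional modes, on the u scale
    n_evals: int

    @property
    def variances(self) -> dict[str, float]:
        return {f: float(s**2) for f, s in zip(self.factor_names, self.sigma)}


def fit_mixed_logit(
    X: np.ndarray,
    y: np.ndarray,
    factors: list[tuple[str, np.ndarray, int]],
    beta_names: list[str] | None = None,
    start_sigma: np.ndarray | None = None,
    xatol: float = 5e-3,
    fatol: float = 5e-4,
    maxfev: int = 400,
    warm: bool = False,
    fixed_sigma: np.ndarray | None = None,
    compute_se: bool = True,
    pirls_tol: float = 1e-10,
) -> MixedLogitFit:
    """Fit the model; ``factors`` is a list of (name, codes, n_levels).

    ``start_sigma`` warm-starts the variance search (pass ``warm=True`` for
    the small initial simplex used in bootstrap refits); ``fixed_sigma``
    skips the variance search entirely and profiles only (beta, v) — with
    all-zero sigma this is exactly ordinary logistic regression.
    Deterministic: the fit involves no randomness.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    k = len(factors)
    if k == 0:
        raise ValueError("at least one random factor is required")
    codes = np.ascontiguousarray(
        np.vstack([np.asarray(c, dtype=np.int64) for _, c, _ in factors])
    )
    qs = np.array([nl for _, _, nl in factors], dtype=np.int64)
    offs = np.concatenate([[0], np.cumsum(qs)[:-1]]).astype(np.int64)
    q = int(qs.sum())
    names = [f for f, _, _ in factors]
    state = {"beta": np.zeros(p), "v": np.zeros(q)}
    cache: dict[tuple, float] = {}
    evals = [0]

    def obj(sig_raw: np.ndarray) -> float:
        sig = np.clip(np.asarray(sig_raw, dtype=np.float64), 0.0, 8.0)
        key = tuple(np.round(sig, 12))
        if key in cache:
            return cache[key]
        evals[0] += 1
        beta = state["beta"].copy()
        v = state["v"].copy()
        m2ll, conv = _pirls(X, y, codes, offs, qs, sig, beta, v, 200, pirls_tol)
        if conv:
            state["beta"], state["v"] = beta, v
        cache[key] = m2ll
        return m2ll

    if fixed_sigma is not None:
        sigma = np.asarray(fixed_sigma, dtype=np.float64)
        obj(sigma)
        outer_ok = True
    else:
        x0 = (
            np.clip(np.asarray(start_sigma, dtype=np.float64), 0.0, 8.0)
            if start_sigma is not None
            else np.full(k, 0.3)
        )
        step = 0.08 if warm else 0.3
        simplex = np.vstack([x0] + [x0 + step * np.eye(k)[i] for i in range(k)])
        res = minimize(
            obj,
            x0,
            method="Nelder-Mead",
            bounds=[(0.0, 8.0)] * k,
            options={
                "xatol": xatol,
                "fatol": fatol,
                "maxfev": maxfev,
                "initial_simplex": simplex,
            },
        )
        sigma = np.clip(res.x, 0.0, 8.0)
        outer_ok = bool(res.success) or res.status == 0
    beta = state["beta"].copy()
    v = state["v"].copy()
    m2ll, inner_conv = _pirls(X, y, codes, offs, qs, sigma, beta, v, 200, min(pirls_tol, 1e-10))
    if compute_se:
        A = _assemble_information(X, y, codes, offs, qs, sigma, beta, v)
        cov = np.linalg.inv(A)
        beta_se = np.sqrt(np.diag(cov)[q:])
    else:
        beta_se = np.full(p, np.nan)
    u = {
        name: sigma[f] * v[offs[f] : offs[f] + qs[f]]
        for f, name in enumerate(names)
    }
    return MixedLogitFit(
        beta=beta,
        beta_names=beta_names or [f"b{j}" for j in range(p)],
        beta_se=beta_se,
        sigma=sigma,
        factor_names=names,
        loglik=-0.5 * m2ll,
        m2ll=float(m2ll),
        converged=bool(inner_conv) and outer_ok,
        n_obs=n,
        n_levels=qs,
        u=u,
        n_evals=evals[0],
    )
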