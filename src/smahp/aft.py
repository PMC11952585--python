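"""Parametric accelerated failure time (AFT) machinery.

Two error families for ``log T = intercept + X beta + b * eps``:

* ``"lognormal"`` — eps standard normal (log-normal survival times);
* ``"weibull"``   — eps standard minimum extreme value (log-Weibull), i.e.
  Weibull survival times with shape ``1/b``.

Provides censored maximum-likelihood fits with observed-information Wald
standard errors (used by the refit and inference steps) and penalized
fits along a warm-started regularization path (used by the screening
step).  The penalized solver works in the concave (beta/b, 1/b)
parametrization, where both censored likelihoods are well behaved, and
uses proximal Newton: quadratic expansion of the likelihood plus
penalized weighted coordinate descent.  The penalty weight is selected
by (extended) BIC on refitted supports or by k-fold cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize, special

__all__ = [
    "AFTFit",
    "RegularizationPath",
    "fit_aft_mle",
    "fit_penalized_aft",
    "cv_penalized_aft",
    "select_lambda_cv",
    "active_set",
    "stratified_folds",
]

_FAMILIES = ("lognormal", "weibull")
_SQRT_2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Censored log-likelihood (value + gradient), parameterized by (beta, log b)
# ---------------------------------------------------------------------------


def _mills_normal(w: np.ndarray) -> np.ndarray:
    """phi(w) / (1 - Phi(w)), computed stably via the scaled complementary erf."""
    return np.sqrt(2.0 / np.pi) / special.erfcx(w / np.sqrt(2.0))


def _loglik_terms(w: np.ndarray, delta: np.ndarray, family: str):
    """Per-observation log-likelihood pieces and d/d_eta, d/d_logb factors.

    Returns (ll, d_eta, d_logb).  ``ll`` omits the -log(b) and -log(t)
    density terms for events (added by the caller), ``d_eta`` satisfies
    dll/deta = d_eta / b, and ``d_logb`` is the derivative of ``ll`` with
    respect to log b (the caller accounts for the -log b term).
    """
    ev = delta == 1
    ll = np.empty_like(w)
    d_eta = np.empty_like(w)
    d_logb = np.empty_like(w)
    if family == "lognormal":
        ll[ev] = -0.5 * w[ev] ** 2 - np.log(_SQRT_2PI)
        ll[~ev] = special.log_ndtr(-w[~ev])
        r = _mills_normal(w[~ev])
        d_eta[ev] = w[ev]
        d_eta[~ev] = r
        d_logb[ev] = w[ev] ** 2
        d_logb[~ev] = w[~ev] * r
    elif family == "weibull":
        wc = np.clip(w, None, 200.0)  # avoid overflow of exp at absurd iterates
        e = np.exp(wc)
        ll[ev] = w[ev] - e[ev]
        ll[~ev] = -e[~ev]
        d_eta[ev] = e[ev] - 1.0
        d_eta[~ev] = e[~ev]
        d_logb[ev] = -w[ev] + w[ev] * e[ev]
        d_logb[~ev] = w[~ev] * e[~ev]
    else:  # pragma: no cover
        raise ValueError(f"unknown family {family!r}")
    return ll, d_eta, d_logb


def _nll_grad(params: np.ndarray, Xd: np.ndarray, logt: np.ndarray,
              delta: np.ndarray, family: str):
    """Negative log-likelihood of T (incl. the 1/t Jacobian) and its gradient.

    ``params = [coefs..., log b]`` where ``Xd`` already contains any
    intercept column.
    """
    beta = params[:-1]
    b = np.exp(params[-1])
    eta = Xd @ beta
    w = (logt - eta) / b
    ll, d_eta, d_logb = _loglik_terms(w, delta, family)
    ev = delta == 1
    nll = -(ll.sum() - ev.sum() * np.log(b) - logt[ev].sum())
    g_eta = d_eta / b                       # dll/deta per observation
    g_beta = -(Xd.T @ g_eta)
    g_logb = -(d_logb.sum() - ev.sum())     # d(-n_ev log b)/dlogb = -n_ev
    if not np.isfinite(nll):
        nll = np.inf
    return nll, np.append(g_beta, g_logb)


@dataclass
class AFTFit:
    """Maximum-likelihood AFT fit (coefficients on the log-time scale)."""

    coef: np.ndarray
    intercept: float
    scale: float
    se: np.ndarray
    intercept_se: float
    loglik: float
    family: str
    converged: bool
    n_iter: int
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coef])


def _check_design(Xd: np.ndarray, names=None):
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # pivoted QR localizes the dependent columns
        from scipy.linalg import qr

        _, r, piv = qr(Xd, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = sorted(piv[rank:])
        labels = [names[i] if names is not None else str(i) for i in bad]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {Xd.shape[1]}); "
            f"offending columns: {labels}"
        )


def fit_aft_mle(features: np.ndarray, time: np.ndarray, delta: np.ndarray,
                family: str = "lognormal", check_rank: bool = True,
                compute_se: bool = True) -> AFTFit:
    """Censored ML fit of a parametric AFT model with an intercept.

    A Newton solve in the concave (beta/b, 1/b) parametrization followed by
    a quasi-Newton (L-BFGS) polish on ``(beta, log b)``; Wald standard
    errors from the inverse observed information (numerical Hessian of the
    negative log-likelihood at the optimum).  ``compute_se=False`` skips
    the Hessian (point estimates only, used by the screening refits).
    Non-convergence is reported via ``converged``/``message``, not raised.
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.size == 0:
        features = np.empty((len(time), 0))
    n, d = features.shape
    time = np.asarray(time, dtype=float)
    delta = np.asarray(delta)
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    if delta.sum() == 0:
        raise ValueError("all observations are censored; the AFT scale is not identifiable")
    if n <= d + 2:
        raise ValueError(f"need n > d + 2 (n={n}, d={d})")
    logt = np.log(time)
    Xd = np.column_stack([np.ones(n), features])
    if d > 0 and check_rank:
        _check_design(Xd)

    # start from least squares on log-times
    beta0, *_ = np.linalg.lstsq(Xd, logt, rcond=None)
    resid = logt - Xd @ beta0
    s0 = max(np.std(resid), 1e-3)

    fam_id = 0 if family == "lognormal" else 1
    Xc = np.ascontiguousarray(features)
    delta_i = np.ascontiguousarray(delta, dtype=np.int64)
    grad = np.empty(d + 2)

    def nll(params):
        f = _nll_grad_nb(params, Xc, logt, delta_i, fam_id, grad)
        return f * n, grad * n

    # Newton solve in the concave parametrization on standardized data
    sd_x = Xc.std(axis=0) if d else np.empty(0)
    sd_x = np.where(sd_x == 0, 1.0, sd_x)
    mu_x = Xc.mean(axis=0) if d else np.empty(0)
    Xstd = np.ascontiguousarray((Xc - mu_x) / sd_x) if d else Xc
    y_m, y_s = float(logt.mean()), float(logt.std()) or 1.0
    ys = np.ascontiguousarray((logt - y_m) / y_s)
    bs_ls, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), Xstd]), ys,
                                rcond=None)
    s_std = max(s0 / y_s, 1e-6)
    v = np.empty(d + 2)
    v[0] = bs_ls[0] / s_std
    v[1:-1] = bs_ls[1:] / s_std
    v[-1] = 1.0 / s_std
    v = _pn_solve_nb(v, Xstd, ys, delta_i, fam_id, 0.0, 0, 3.0, 0.5,
                     1e-10, 100, 200)
    x0 = np.empty(d + 2)
    coef_std = y_s * v[1:-1] / (v[-1] * sd_x) if d else np.empty(0)
    x0[1:-1] = coef_std
    x0[0] = y_m + y_s * v[0] / v[-1] - float(coef_std @ mu_x) if d \
        else y_m + y_s * v[0] / v[-1]
    x0[-1] = np.log(y_s / v[-1])
    # short quasi-Newton polish on (beta, log b); the scale is bounded away
    # from 0 (with many features and few events the censored likelihood is
    # otherwise unbounded: event interpolation with b -> 0)
    bounds = [(None, None)] * (d + 1) + [(np.log(s0) + np.log(0.01), None)]
    res = optimize.minimize(
        nll, x0, jac=True, bounds=bounds,
        method="L-BFGS-B", options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    f_start, _ = nll(x0)
    params = res.x if res.fun <= f_start else x0
    converged = bool(res.success)
    message = str(res.message)
    if not converged:
        # L-BFGS line searches can fail when started at the optimum; accept
        # the point if the score equations are satisfied
        _, g_here = nll(params)
        if np.max(np.abs(g_here)) / n < 1e-5:
            converged = True
            message = "converged (score equations satisfied)"
    if not compute_se:
        se_all = np.full(d + 2, np.nan)
    else:
        hess = _numeric_hessian(params, nll)
        try:
            cov = np.linalg.inv(hess)
            se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            if converged and np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            if converged:
                raise ValueError(
                    "singular observed information; check for collinear columns"
                ) from None
            se_all = np.full(d + 2, np.nan)
    return AFTFit(
        coef=params[1:-1].copy(),
        intercept=float(params[0]),
        scale=float(np.exp(params[-1])),
        se=se_all[1:-1].copy(),
        intercept_se=float(se_all[0]),
        loglik=float(-res.fun),
        family=family,
        converged=converged,
        n_iter=int(res.nit),
        message=message,
    )


def _numeric_hessian(params, nll) -> np.ndarray:
    """Central-difference Jacobian of the analytic gradient (symmetrized)."""
    m = len(params)
    h = np.maximum(1e-5, 1e-5 * np.abs(params))
    H = np.empty((m, m))
    for i in range(m):
        up = params.copy(); up[i] += h[i]
        dn = params.copy(); dn[i] -= h[i]
        _, gu = nll(up)
        _, gd = nll(dn)
        H[i] = (gu - gd) / (2 * h[i])
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Penalized path: proximal gradient (FISTA with backtracking + warm starts)
# ---------------------------------------------------------------------------


@dataclass
class RegularizationPath:
    """Coefficient path of a penalized AFT fit over a decreasing lambda grid."""

    lambdas: np.ndarray
    coefs: np.ndarray          # n_lambda x d, on the input feature scale
    intercepts: np.ndarray
    scales: np.ndarray
    penalty: str
    family: str
    cv_scores: np.ndarray | None = None
    lambda_selected: float | None = None
    feature_means: np.ndarray = field(default=None, repr=False)
    feature_sds: np.ndarray = field(default=None, repr=False)

    def coef_at(self, lam: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        if not np.isclose(self.lambdas[idx], lam, rtol=1e-10, atol=1e-15):
            raise ValueError(f"lambda {lam} not on the grid")
        return self.coefs[idx]


def _fit_null(logt, delta, family):
    """Intercept + scale only fit; starting point of every path."""
    fit = fit_aft_mle(np.empty((len(logt), 0)), np.exp(logt), delta, family)
    return fit.intercept, np.log(fit.scale)


def fit_penalized_aft(features: np.ndarray, time: np.ndarray, delta: np.ndarray,
                      family: str = "lognormal", penalty: str = "lasso",
                      lambdas: np.ndarray | None = None, gamma: float = 3.0,
                      n_lambda: int = 100, lambda_min_ratio: float = 1e-2,
                      alpha_mix: float = 0.5, tol: float = 1e-6,
                      max_iter: int = 10_000, dfmax: int | None = None
                      ) -> RegularizationPath:
    """Penalized AFT fit along a decreasing lambda grid with warm starts.

    Features and log-times are standardized internally (coefficients are
    reported on the input scale); the intercept and the scale are never
    penalized.  The solver works in the concave (beta/b, 1/b)
    parametrization, where the censored AFT likelihood has no degenerate
    scale-collapse direction and the l1 penalty is scale-relative.  The
    grid runs from the smallest lambda that zeroes every coefficient down
    to ``lambda_min_ratio`` times it; the path stops early once the active
    set exceeds ``dfmax`` (default ``0.8 * n``), where fits saturate.
    """
    features = np.asarray(features, dtype=float)
    time = np.asarray(time, dtype=float)
    delta = np.asarray(delta)
    n, d = features.shape
    if delta.sum() == 0:
        raise ValueError("all observations are censored")
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"constant feature columns: {bad}")
    Xs = np.ascontiguousarray((features - mu) / sd)
    logt = np.log(time)
    y_mean = float(logt.mean())
    y_sd = float(logt.std()) or 1.0
    ys = np.ascontiguousarray((logt - y_mean) / y_sd)

    b0, logb0 = _fit_null(ys, delta, family)
    v = np.zeros(d + 2)
    v[0] = b0 / np.exp(logb0)              # theta0 = mu_null / b_null
    v[-1] = np.exp(-logb0)                 # phi = 1 / b_null
    fam_id = 0 if family == "lognormal" else 1
    pen_id = {"lasso": 0, "mcp": 1, "enet": 2}[penalty]
    delta_i = np.ascontiguousarray(delta, dtype=np.int64)
    g0 = np.empty(d + 2)
    _nll_grad_theta_nb(v, Xs, ys, delta_i, fam_id, g0)
    lam_max = float(np.max(np.abs(g0[1:-1])))
    if penalty == "enet":
        lam_max /= alpha_mix
    if lambdas is None:
        lam_max = max(lam_max, 1e-10)
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(lambdas < 0):
            raise ValueError("lambda grid must be non-negative")
        if np.any(np.diff(lambdas) > 0):
            raise ValueError("lambda grid must be decreasing")
    if dfmax is None:
        dfmax = max(10, n // 2)
    dfmax = min(dfmax, d)

    coefs, intercepts, scales, used = [], [], [], []
    max_sweeps = max(50, min(max_iter, 500))
    for lam in lambdas:
        v = _pn_solve_nb(v, Xs, ys, delta_i, fam_id, float(lam), pen_id,
                         gamma, alpha_mix, tol, 50, max_sweeps)
        v[1:-1][np.abs(v[1:-1]) < 1e-9] = 0.0     # numerical dust
        used.append(lam)
        # back-transform: b = y_sd/phi, beta_j = y_sd * theta_j / (phi * sd_j)
        phi = v[-1]
        coef = y_sd * v[1:-1] / (phi * sd)
        coefs.append(coef)
        intercepts.append(y_mean + y_sd * v[0] / phi - float(coef @ mu))
        scales.append(y_sd / phi)
        if np.count_nonzero(np.abs(v[1:-1]) > 1e-8) > dfmax:
            break
    return RegularizationPath(
        lambdas=np.array(used), coefs=np.array(coefs),
        intercepts=np.array(intercepts), scales=np.array(scales),
        penalty=penalty, family=family, feature_means=mu, feature_sds=sd,
    )


# -- numba kernels for the proximal-gradient solver -------------------------

_LOG_SQRT_2PI = float(np.log(np.sqrt(2.0 * np.pi)))
_LOG_HALF = float(np.log(0.5))
_SQRT_PI = float(np.sqrt(np.pi))


@njit(cache=True)
def _log_ndtr_nb(t: float) -> float:
    """log Phi(t), stable in the far left tail."""
    u = -t / np.sqrt(2.0)
    if u < 25.0:
        v = 0.5 * math.erfc(u)
        if v > 0.0:
            return math.log(v)
    # asymptotic erfc(u) ~ exp(-u^2)/(u sqrt(pi)) (1 - 1/(2u^2) + 3/(4u^4))
    return _LOG_HALF - u * u - math.log(u * _SQRT_PI) \
        + math.log(1.0 - 0.5 / (u * u) + 0.75 / (u ** 4))


@njit(cache=True)
def _nll_grad_theta_nb(v, Xs, ys, delta, fam, g):
    """Average negative log-likelihood and gradient in the concave
    parametrization ``v = [theta0, theta..., phi]`` with ``theta = beta/b``
    and ``phi = 1/b``, response standardized to ``ys``.

    In these coordinates the censored lognormal and log-Weibull AFT
    likelihoods are concave, so the penalized path has no degenerate
    scale-collapse basin.
    """
    n, d = Xs.shape
    phi = v[d + 1]
    f = 0.0
    g_phi = 0.0
    ge = np.empty(n)
    for i in range(n):
        eta = v[0]
        for j in range(d):
            eta += Xs[i, j] * v[1 + j]
        w = phi * ys[i] - eta
        if fam == 0:                        # lognormal
            if delta[i] == 1:
                f -= math.log(phi) - 0.5 * w * w - _LOG_SQRT_2PI
                ge[i] = w
                g_phi += 1.0 / phi - w * ys[i]
            else:
                ls = _log_ndtr_nb(-w)
                f -= ls
                r = math.exp(-0.5 * w * w - _LOG_SQRT_2PI - ls)
                ge[i] = r
                g_phi += -r * ys[i]
        else:                               # weibull (extreme value)
            wc = w if w < 200.0 else 200.0
            e = math.exp(wc)
            if delta[i] == 1:
                f -= math.log(phi) + w - e
                ge[i] = e - 1.0
                g_phi += 1.0 / phi + (1.0 - e) * ys[i]
            else:
                f -= -e
                ge[i] = e
                g_phi += -e * ys[i]
    f /= n
    s = 0.0
    for i in range(n):
        s += ge[i]
    g[0] = -s / n
    for j in range(d):
        acc = 0.0
        for i in range(n):
            acc += Xs[i, j] * ge[i]
        g[1 + j] = -acc / n
    g[d + 1] = -g_phi / n
    return f


@njit(cache=True)
def _nll_grad_nb(u, Xs, logt, delta, fam, g):
    """Average negative log-likelihood and gradient, standardized coordinates.

    ``u = [intercept, beta..., log b]``; ``g`` is written in place.
    """
    n, d = Xs.shape
    logb = u[d + 1]
    inv_b = math.exp(-logb)
    f = 0.0
    g_logb = 0.0
    n_ev = 0
    ge = np.empty(n)
    for i in range(n):
        eta = u[0]
        for j in range(d):
            eta += Xs[i, j] * u[1 + j]
        w = (logt[i] - eta) * inv_b
        if fam == 0:                        # lognormal
            if delta[i] == 1:
                n_ev += 1
                f -= -0.5 * w * w - _LOG_SQRT_2PI - logb - logt[i]
                ge[i] = w
                g_logb += w * w
            else:
                ls = _log_ndtr_nb(-w)
                f -= ls
                r = math.exp(-0.5 * w * w - _LOG_SQRT_2PI - ls)
                ge[i] = r
                g_logb += w * r
        else:                               # weibull (extreme value)
            wc = w if w < 200.0 else 200.0
            e = math.exp(wc)
            if delta[i] == 1:
                n_ev += 1
                f -= w - e - logb - logt[i]
                ge[i] = e - 1.0
                g_logb += -w + w * e
            else:
                f -= -e
                ge[i] = e
                g_logb += w * e
    f /= n
    s = 0.0
    for i in range(n):
        s += ge[i]
    g[0] = -s * inv_b / n
    for j in range(d):
        acc = 0.0
        for i in range(n):
            acc += Xs[i, j] * ge[i]
        g[1 + j] = -acc * inv_b / n
    g[d + 1] = -(g_logb - n_ev) / n
    return f


@njit(cache=True)
def _penalty_nb(u, lam, pen_id, gamma, alpha_mix):
    d = u.shape[0] - 2
    val = 0.0
    for j in range(1, d + 1):
        a = abs(u[j])
        if pen_id == 0:
            val += lam * a
        elif pen_id == 1:
            val += lam * a - a * a / (2.0 * gamma) if a <= gamma * lam \
                else 0.5 * gamma * lam * lam
        else:
            val += lam * (alpha_mix * a + 0.5 * (1.0 - alpha_mix) * a * a)
    return val


@njit(cache=True)
def _pn_derivs_nb(w, delta, fam, d1, d2):
    """First/second derivatives of the per-observation NLL piece h(w).

    ``h`` excludes the -log(phi) event term (handled analytically by the
    caller).  Returns the summed h values.
    """
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        if fam == 0:                        # lognormal
            if delta[i] == 1:
                total += 0.5 * w[i] * w[i] + _LOG_SQRT_2PI
                d1[i] = w[i]
                d2[i] = 1.0
            else:
                ls = _log_ndtr_nb(-w[i])
                total += -ls
                r = math.exp(-0.5 * w[i] * w[i] - _LOG_SQRT_2PI - ls)
                d1[i] = r
                d2[i] = r * (r - w[i])
        else:                               # weibull (extreme value)
            wc = w[i] if w[i] < 200.0 else 200.0
            e = math.exp(wc)
            if delta[i] == 1:
                total += e - w[i]
                d1[i] = e - 1.0
                d2[i] = e
            else:
                total += e
                d1[i] = e
                d2[i] = e
    return total


@njit(cache=True)
def _pn_objective_nb(v, Xs, ys, delta, fam, w_buf):
    """Average NLL at v (fills w_buf with the linear predictor w)."""
    n, d = Xs.shape
    phi = v[d + 1]
    total = 0.0
    n_ev = 0
    for i in range(n):
        eta = v[0]
        for j in range(d):
            eta += Xs[i, j] * v[1 + j]
        w = phi * ys[i] - eta
        w_buf[i] = w
        if fam == 0:
            if delta[i] == 1:
                n_ev += 1
                total += 0.5 * w * w + _LOG_SQRT_2PI
            else:
                total += -_log_ndtr_nb(-w)
        else:
            wc = w if w < 200.0 else 200.0
            e = math.exp(wc)
            if delta[i] == 1:
                n_ev += 1
                total += e - w
            else:
                total += e
    if n_ev > 0:
        total -= n_ev * math.log(phi)
    return total / n


@njit(cache=True)
def _pn_update(q, A, lam, pen_id, gamma, alpha_mix):
    """Penalized coordinate minimizer of 0.5*A*(x-q)^2 + penalty(x)."""
    Aq = A * q
    a = abs(Aq)
    if pen_id == 0:                        # lasso
        if a <= lam:
            return 0.0
        return math.copysign(a - lam, q) / A
    if pen_id == 1:                        # mcp
        if a <= lam:
            return 0.0
        denom = A - 1.0 / gamma
        if denom <= 1e-8:
            denom = 1e-8
        x = math.copysign(a - lam, q) / denom
        if abs(x) > gamma * lam:
            return q
        return x
    thr = lam * alpha_mix                  # enet
    if a <= thr:
        return 0.0
    return math.copysign(a - thr, q) / (A + lam * (1.0 - alpha_mix))


@njit(cache=True)
def _pn_sweep(xi, r, Xs, ys, d1, d2, n_ev, phi0, lam, pen_id, gamma,
              alpha_mix, active_only):
    """One coordinate-descent sweep on the quadratic model.

    ``xi`` is the candidate point, ``r[i]`` the accumulated change of the
    linear predictor w relative to the expansion point.  Columns of the
    linear predictor: -1 for theta0, -Xs[:, j] for theta_j, ys for phi.
    Returns the largest coefficient change.
    """
    n, d = Xs.shape
    inv_n = 1.0 / n
    max_diff = 0.0
    # theta0 (unpenalized, column -1)
    grad = 0.0
    A = 0.0
    for i in range(n):
        grad -= (d1[i] + d2[i] * r[i]) * inv_n
        A += d2[i] * inv_n
    if A > 1e-12:
        new = xi[0] - grad / A
        diff = new - xi[0]
        if abs(diff) > 1e-300:
            for i in range(n):
                r[i] -= diff
            if abs(diff) > max_diff:
                max_diff = abs(diff)
            xi[0] = new
    # penalized thetas
    for j in range(1, d + 1):
        if active_only and xi[j] == 0.0:
            continue
        grad = 0.0
        A = 0.0
        for i in range(n):
            zc = -Xs[i, j - 1]
            grad += (d1[i] + d2[i] * r[i]) * zc * inv_n
            A += d2[i] * zc * zc * inv_n
        if A <= 1e-12:
            continue
        q = xi[j] - grad / A
        new = _pn_update(q, A, lam, pen_id, gamma, alpha_mix)
        diff = new - xi[j]
        if diff != 0.0:
            for i in range(n):
                r[i] += (-Xs[i, j - 1]) * diff
            if abs(diff) > max_diff:
                max_diff = abs(diff)
            xi[j] = new
    # phi (unpenalized, column ys, plus the -n_ev log(phi) curvature)
    grad = 0.0
    A = 0.0
    for i in range(n):
        grad += (d1[i] + d2[i] * r[i]) * ys[i] * inv_n
        A += d2[i] * ys[i] * ys[i] * inv_n
    # quadratic expansion of -n_ev log(phi) around phi0:
    # grad at xi: -n_ev/phi0 + n_ev/phi0^2 (xi_phi - phi0); hess: n_ev/phi0^2
    grad += n_ev * inv_n * ((xi[d + 1] - phi0) / (phi0 * phi0) - 1.0 / phi0)
    A += n_ev * inv_n / (phi0 * phi0)
    if A > 1e-12:
        new = xi[d + 1] - grad / A
        if new < 1e-10:
            new = 1e-10
        diff = new - xi[d + 1]
        if abs(diff) > 1e-300:
            for i in range(n):
                r[i] += ys[i] * diff
            if abs(diff) > max_diff:
                max_diff = abs(diff)
            xi[d + 1] = new
    return max_diff


@njit(cache=True)
def _pn_solve_nb(v0, Xs, ys, delta, fam, lam, pen_id, gamma, alpha_mix,
                 tol, max_outer, max_sweeps):
    """Proximal-Newton solve of one penalized AFT problem (warm start v0).

    Outer loop: quadratic expansion of the average NLL at the current
    point; inner loop: coordinate descent on the penalized quadratic
    (active-set strategy); step halving on the true objective.
    """
    n, d = Xs.shape
    m = d + 2
    v = v0.copy()
    w = np.empty(n)
    d1 = np.empty(n)
    d2 = np.empty(n)
    r = np.empty(n)
    xi = np.empty(m)
    n_ev = 0
    for i in range(n):
        if delta[i] == 1:
            n_ev += 1
    f = _pn_objective_nb(v, Xs, ys, delta, fam, w)
    F = f + _penalty_nb(v, lam, pen_id, gamma, alpha_mix)
    for _ in range(max_outer):
        _pn_derivs_nb(w, delta, fam, d1, d2)
        for i in range(n):
            if d2[i] < 1e-6:
                d2[i] = 1e-6
            r[i] = 0.0
        for c in range(m):
            xi[c] = v[c]
        phi0 = v[d + 1]
        sweeps = 0
        while sweeps < max_sweeps:
            diff_full = _pn_sweep(xi, r, Xs, ys, d1, d2, n_ev, phi0, lam,
                                  pen_id, gamma, alpha_mix, False)
            sweeps += 1
            if diff_full < 1e-6:
                break
            while sweeps < max_sweeps:
                diff_act = _pn_sweep(xi, r, Xs, ys, d1, d2, n_ev, phi0, lam,
                                     pen_id, gamma, alpha_mix, True)
                sweeps += 1
                if diff_act < 1e-6:
                    break
        # step halving on the true penalized objective; the Newton
        # direction xi - v is kept fixed while the step shrinks
        direction = np.empty(m)
        for c in range(m):
            direction[c] = xi[c] - v[c]
        step = 1.0
        F_new = F
        accepted = False
        for _ls in range(30):
            for c in range(m):
                xi[c] = v[c] + step * direction[c]
            if xi[d + 1] < 1e-10:
                xi[d + 1] = 1e-10
            f_new = _pn_objective_nb(xi, Xs, ys, delta, fam, w)
            F_try = f_new + _penalty_nb(xi, lam, pen_id, gamma, alpha_mix)
            if F_try <= F + 1e-12:
                F_new = F_try
                accepted = True
                break
            step *= 0.5
        if not accepted:
            _pn_objective_nb(v, Xs, ys, delta, fam, w)   # restore w at v
            break
        converged = abs(F - F_new) <= tol * max(1.0, abs(F_new))
        for c in range(m):
            v[c] = xi[c]
        F = F_new
        if converged:
            break
    return v


def active_set(path: RegularizationPath, lam: float, tol: float = 1e-8) -> list[int]:
    """Indices of coefficients with |value| above tolerance at grid point lam."""
    coef = path.coef_at(lam)
    scale = path.feature_sds if path.feature_sds is not None else 1.0
    return sorted(np.flatnonzero(np.abs(coef * scale) > tol).tolist())


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment stratified on a binary label (round-robin after shuffle)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assign = np.empty(len(labels), dtype=int)
    offset = 0
    for val in np.unique(labels):
        idx = np.flatnonzero(labels == val)
        rng.shuffle(idx)
        assign[idx] = (np.arange(len(idx)) + offset) % n_folds
        offset += len(idx)
    return assign


def select_lambda_cv(path_builder, score_path, n_obs: int, folds: int = 5,
                     stratify: np.ndarray | None = None, seed: int = 0,
                     rule: str = "min"):
    """Generic k-fold CV over a shared decreasing lambda grid.

    ``path_builder(train_idx)`` returns a :class:`RegularizationPath` fitted
    on the training rows; ``score_path(path, test_idx)`` returns the
    per-lambda held-out loss.  Only lambdas computed in every fold (paths
    may stop early) enter the comparison.  Ties in the mean CV loss are
    broken toward the larger lambda.  ``rule="1se"`` picks the largest
    lambda whose mean loss is within one fold-to-fold standard error of the
    minimum (the usual parsimony rule for screening fits).
    """
    if folds < 3:
        raise ValueError("need at least 3 folds")
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    strat = stratify if stratify is not None else np.zeros(n_obs, dtype=int)
    assign = stratified_folds(strat, folds, seed)
    losses, grids = [], []
    for f in range(folds):
        train = np.flatnonzero(assign != f)
        test = np.flatnonzero(assign == f)
        path = path_builder(train)
        losses.append(np.asarray(score_path(path, test), dtype=float))
        grids.append(path.lambdas)
    m = min(len(l) for l in losses)
    stacked = np.array([l[:m] for l in losses])
    cv = stacked.mean(axis=0)
    best = int(np.argmin(cv))           # grids decrease, argmin takes first = largest
    if rule == "1se":
        se = stacked.std(axis=0, ddof=1) / np.sqrt(folds)
        within = np.flatnonzero(cv[: best + 1] <= cv[best] + se[best])
        best = int(within[0]) if within.size else best
    return grids[0][best], cv, grids[0][:m]


def cv_penalized_aft(features, time, delta, family: str = "lognormal",
                     penalty: str = "lasso", n_folds: int = 5, seed: int = 0,
                     rule: str = "min", **path_kwargs) -> RegularizationPath:
    """Penalized AFT path with the selected lambda attached.

    ``rule="min"``/``"1se"``: k-fold CV on the held-out censored negative
    log-likelihood (grid built once on the full data; fold paths reuse it
    so the curve is comparable across folds).  ``rule="bic"``: no folds --
    lambda minimizes ``2 * NLL + df * log(n)`` along the full-data path
    (the conservative screening selector).
    """
    features = np.asarray(features, dtype=float)
    time = np.asarray(time, dtype=float)
    delta = np.asarray(delta)
    full = fit_penalized_aft(features, time, delta, family=family,
                             penalty=penalty, **path_kwargs)
    logt = np.log(time)
    n = len(time)

    if rule in ("bic", "ebic"):
        d = features.shape[1]
        # information criteria are evaluated on unpenalized refits of each
        # support along the path (shrinkage otherwise lets correlated null
        # features buy spurious likelihood); extended-BIC complexity term
        # (gamma = 1): 2 log C(d, df)
        from scipy.special import gammaln

        bic = np.full(len(full.lambdas), np.inf)
        cache: dict[tuple, float] = {}
        best_df = 0
        for i in range(len(full.lambdas)):
            support = tuple(np.flatnonzero(
                np.abs(full.coefs[i] * full.feature_sds) > 1e-8))
            df = len(support)
            if df + 4 >= n:
                continue
            if support in cache:
                nll = cache[support]
            else:
                refit = fit_aft_mle(features[:, list(support)], time, delta,
                                    family=family, check_rank=False,
                                    compute_se=False)
                nll = -refit.loglik
                cache[support] = nll
            bic[i] = 2.0 * nll + (df + 2) * np.log(n)
            if rule == "ebic":
                bic[i] += 2.0 * (gammaln(d + 1) - gammaln(df + 1)
                                 - gammaln(d - df + 1))
            cur_best = float(np.min(bic[: i + 1]))
            if bic[i] == cur_best:
                best_df = df
            # deep past the minimum the criterion only grows with df; the
            # complexity terms alone dwarf any attainable likelihood gain
            if df > max(40, best_df + 15) or (
                    df > best_df + 15 and bic[i] > cur_best + 20.0 * np.log(n)):
                break
        best = int(np.argmin(bic))
        full.cv_scores = bic
        full.lambda_selected = float(full.lambdas[best])
        return full

    def builder(train_idx):
        return fit_penalized_aft(
            features[train_idx], time[train_idx], delta[train_idx],
            family=family, penalty=penalty,
            **{**path_kwargs, "lambdas": full.lambdas},
        )

    def scorer(path, test_idx):
        Xte = features[test_idx]
        lt, dl = logt[test_idx], delta[test_idx]
        out = np.empty(len(path.lambdas))
        ev = dl == 1
        for i in range(len(path.lambdas)):
            eta = path.intercepts[i] + Xte @ path.coefs[i]
            b = path.scales[i]
            w = (lt - eta) / b
            ll, _, _ = _loglik_terms(w, dl, path.family)
            out[i] = -(ll.sum() - ev.sum() * np.log(b) - lt[ev].sum()) / len(test_idx)
        return out

    lam_sel, cv, _ = select_lambda_cv(builder, scorer, len(time),
                                      folds=n_folds, stratify=delta,
                                      seed=seed, rule=rule)
    full.cv_scores = cv
    full.lambda_selected = float(lam_sel)
    return full
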