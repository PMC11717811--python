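"""REML estimation for linear models with nested random intercepts.

Covers exactly the two structures the migration analysis needs:

* random intercepts for litter and for slice nested within litter, or
* a litter intercept alone (per-slice count summaries).

The covariance of each litter block is
``sigma2_e * (I + g_l * J + g_s * blockdiag(J_slice))`` with variance
ratios ``g = sigma2_level / sigma2_e``. The residual variance is profiled
out and the REML criterion is minimized over log variance ratios.

Denominator degrees of freedom for Wald t/F tests use a Satterthwaite
approximation computed by finite differences of the unprofiled REML
log-likelihood; when that fails (boundary fits, singular information) a
containment-style df supplied by the caller is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ComputationError, ParameterError

_BOUNDARY_RATIO = 1e-6


@dataclass
class LMMResult:
    """Fitted nested random-intercept model."""

    beta: pd.Series
    cov_beta: np.ndarray
    sigma2_resid: float
    sigma2_litter: float | None
    sigma2_slice: float | None
    neg2_reml: float
    converged: bool
    n_obs: int
    n_litters: int
    n_slices: int | None
    warnings: list[str] = field(default_factory=list)
    # internal references for df computations
    _X: np.ndarray | None = None
    _y: np.ndarray | None = None
    _litter: np.ndarray | None = None
    _slice: np.ndarray | None = None
    _ws: object = None
    _vcov_cache: dict = field(default_factory=dict)

    @property
    def df_containment(self) -> int:
        """Fallback denominator df: treatment varies at the innermost grouped level."""
        p = self._X.shape[1]
        if self.n_slices is not None:
            return max(self.n_slices - self.n_litters - (p - 1), 1)
        return max(self.n_obs - self.n_litters - (p - 1), 1)


def _group_rows(codes: np.ndarray) -> list[np.ndarray]:
    order = {}
    for i, c in enumerate(codes):
        order.setdefault(c, []).append(i)
    return [np.asarray(v) for v in order.values()]


_TINY_RATIO = 1e-14


class _Workspace:
    """Precomputed per-litter crossproducts of the design.

    Each litter block has covariance U = I + Z diag(d) Z' with Z the
    [litter-ones | slice-indicator] columns and d = (g_l, g_s, ..., g_s).
    All solves go through the Woodbury identity, so a likelihood
    evaluation costs O(m^3) in the number of random-effect columns per
    block, not O(n^3) in cells.
    """

    def __init__(self, y, X, litter, slice_codes):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.litter = np.asarray(litter)
        self.slice_codes = np.asarray(slice_codes) if slice_codes is not None else None
        self.groups = _group_rows(self.litter)
        self.has_slice = self.slice_codes is not None

        self.xtx_total = np.zeros((self.p, self.p))
        self.xty_total = np.zeros(self.p)
        self.yty_total = 0.0
        per_block = {}
        for rows in self.groups:
            Xi = self.X[rows]
            yi = self.y[rows]
            n_i = len(rows)
            self.xtx_total += Xi.T @ Xi
            self.xty_total += Xi.T @ yi
            self.yty_total += float(yi @ yi)
            cols = [np.ones(n_i)]
            if self.has_slice:
                sc = self.slice_codes[rows]
                for s in pd.unique(sc):
                    cols.append((sc == s).astype(float))
            Zi = np.column_stack(cols)
            m = Zi.shape[1]
            per_block.setdefault(m, []).append((Zi.T @ Zi, Zi.T @ Xi, Zi.T @ yi))
        # stack blocks with equal random-effect column counts for batched solves
        self._stacks = [
            (
                m,
                np.stack([b[0] for b in blocks]),
                np.stack([b[1] for b in blocks]),
                np.stack([b[2] for b in blocks]),
            )
            for m, blocks in per_block.items()
        ]

    def whitened_crossprods(self, g_l: float, g_s: float):
        """Return (XtWX, XtWy, ytWy, sum log|U_i|) for U = V / sigma2_e."""
        p = self.p
        xtwx = self.xtx_total.copy()
        xtwy = self.xty_total.copy()
        ytwy = self.yty_total
        logdet = 0.0
        use_l = g_l > _TINY_RATIO
        use_s = self.has_slice and g_s > _TINY_RATIO
        if not use_l and not use_s:
            return xtwx, xtwy, ytwy, logdet
        for m, ztz, ztx, zty in self._stacks:
            idx = ([0] if use_l else []) + (list(range(1, m)) if use_s else [])
            dvec = ([g_l] if use_l else []) + ([g_s] * (m - 1) if use_s else [])
            idx = np.asarray(idx)
            dvec = np.asarray(dvec)
            a = ztz[:, idx[:, None], idx[None, :]] + np.diag(1.0 / dvec)
            sign, ld = np.linalg.slogdet(a)
            if np.any(sign <= 0):
                return np.full((p, p), np.nan), np.full(p, np.nan), np.nan, np.nan
            n_blocks = a.shape[0]
            logdet += float(ld.sum()) + n_blocks * float(np.sum(np.log(dvec)))
            ztx_a = ztx[:, idx, :]
            zty_a = zty[:, idx]
            rhs = np.concatenate([ztx_a, zty_a[:, :, None]], axis=2)
            sol = np.linalg.solve(a, rhs)
            xtwx -= np.einsum("bmp,bmq->pq", ztx_a, sol[:, :, :p])
            xtwy -= np.einsum("bmp,bm->p", ztx_a, sol[:, :, p])
            ytwy -= float(np.einsum("bm,bm->", zty_a, sol[:, :, p]))
        return xtwx, xtwy, ytwy, logdet


def _profiled_neg2(ws: _Workspace, g_l: float, g_s: float):
    xtwx, xtwy, ytwy, logdet = ws.whitened_crossprods(g_l, g_s)
    if not np.isfinite(logdet):
        return np.inf, None
    sign, logdet_x = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf, None
    beta = np.linalg.solve(xtwx, xtwy)
    rss = ytwy - beta @ xtwy
    if rss <= 0:
        return np.inf, None
    dfres = ws.n - ws.p
    sigma2 = rss / dfres
    neg2 = dfres * np.log(sigma2) + logdet + logdet_x + dfres
    return neg2, (beta, sigma2, xtwx)


def fit_lmm(
    y,
    X,
    exog_names: list[str],
    litter,
    slice_codes=None,
    allow_fallback: bool = True,
) -> LMMResult:
    """Fit by REML; on optimizer failure drop the slice effect, then litter.

    Parameters
    ----------
    y : array of outcomes (already transformed; the caller owns the log).
    X : fixed-effect design matrix, first column typically an intercept.
    litter, slice_codes : group identifiers per row; slice ids must be
        unique across litters (nesting is taken from the ids themselves).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ParameterError("y and X are not conformable")
    litter = np.asarray(litter)
    if len(np.unique(litter)) < 2:
        raise ParameterError("need >= 2 litters")

    warnings_log: list[str] = []
    ws = _Workspace(y, X, litter, slice_codes)

    def objective(log_g):
        g_l = float(np.exp(log_g[0]))
        g_s = float(np.exp(log_g[1])) if ws.has_slice else 0.0
        val, _ = _profiled_neg2(ws, g_l, g_s)
        return val

    ndim = 2 if ws.has_slice else 1
    best = None
    starts = ([-0.7] * ndim, [-3.0] * ndim, [1.0] * ndim)
    for k, start in enumerate(starts):
        try:
            res = optimize.minimize(
                objective,
                np.array(start),
                method="Nelder-Mead",
                bounds=[(-18.0, 8.0)] * ndim,
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 1000},
            )
        except Exception:  # numerical failure on this start
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        # extra starts only guard against a failed or boundary-stuck first fit
        if k == 0 and best is not None and best.success and np.all(best.x > -16.0):
            break

    if best is None or not np.isfinite(best.fun):
        if allow_fallback and ws.has_slice:
            warnings_log.append("slice variance component dropped (fit failure)")
            sub = fit_lmm(y, X, exog_names, litter, None, allow_fallback=True)
            sub.warnings = warnings_log + sub.warnings
            return sub
        if allow_fallback:
            warnings_log.append("litter variance component dropped (fit failure); OLS fit")
            return _ols_result(y, X, exog_names, litter, warnings_log)
        raise ComputationError("REML optimization failed")

    g_l = float(np.exp(best.x[0]))
    g_s = float(np.exp(best.x[1])) if ws.has_slice else 0.0
    neg2, (beta, sigma2, xtwx) = _profiled_neg2(ws, g_l, g_s)
    if g_l < _BOUNDARY_RATIO:
        warnings_log.append("litter variance estimated at the zero boundary")
    if ws.has_slice and g_s < _BOUNDARY_RATIO:
        warnings_log.append("slice variance estimated at the zero boundary")

    cov_beta = sigma2 * np.linalg.inv(xtwx)
    return LMMResult(
        beta=pd.Series(beta, index=exog_names),
        cov_beta=cov_beta,
        sigma2_resid=float(sigma2),
        sigma2_litter=float(g_l * sigma2),
        sigma2_slice=float(g_s * sigma2) if ws.has_slice else None,
        neg2_reml=float(neg2),
        converged=bool(best.success),
        n_obs=ws.n,
        n_litters=len(ws.groups),
        n_slices=len(np.unique(ws.slice_codes)) if ws.has_slice else None,
        warnings=warnings_log,
        _X=X,
        _y=y,
        _litter=litter,
        _slice=np.asarray(slice_codes) if slice_codes is not None else None,
        _ws=ws,
    )


def _ols_result(y, X, exog_names, litter, warnings_log) -> LMMResult:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dfres = max(len(y) - rank, 1)
    sigma2 = float(resid @ resid) / dfres
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return LMMResult(
        beta=pd.Series(beta, index=exog_names),
        cov_beta=cov,
        sigma2_resid=sigma2,
        sigma2_litter=None,
        sigma2_slice=None,
        neg2_reml=float("nan"),
        converged=True,
        n_obs=len(y),
        n_litters=len(np.unique(litter)),
        n_slices=None,
        warnings=warnings_log,
        _X=np.asarray(X, float),
        _y=np.asarray(y, float),
        _litter=np.asarray(litter),
        _slice=None,
    )


# ---------------------------------------------------------------------------
# Satterthwaite machinery
# ---------------------------------------------------------------------------

def _theta_hat(result: LMMResult) -> tuple[np.ndarray, list[str]]:
    """Active variance parameters on the log scale (boundary components excluded)."""
    theta = [np.log(result.sigma2_resid)]
    names = ["resid"]
    if result.sigma2_litter is not None and result.sigma2_litter > _BOUNDARY_RATIO * result.sigma2_resid:
        theta.append(np.log(result.sigma2_litter))
        names.append("litter")
    if result.sigma2_slice is not None and result.sigma2_slice > _BOUNDARY_RATIO * result.sigma2_resid:
        theta.append(np.log(result.sigma2_slice))
        names.append("slice")
    return np.asarray(theta), names


def _unpack(theta: np.ndarray, names: list[str]) -> tuple[float, float, float]:
    s2 = dict(zip(names, np.exp(theta)))
    return s2["resid"], s2.get("litter", 0.0), s2.get("slice", 0.0)


def _crossprods_at(result: LMMResult, s2_e, s2_l, s2_s):
    ws = result._ws
    if ws is None:
        ws = result._ws = _Workspace(result._y, result._X, result._litter, result._slice)
    g_l = s2_l / s2_e
    g_s = s2_s / s2_e
    xtwx, xtwy, ytwy, logdet_u = ws.whitened_crossprods(g_l, g_s)
    return ws, xtwx / s2_e, xtwy / s2_e, ytwy / s2_e, logdet_u + ws.n * np.log(s2_e)


def _cov_beta_at(result: LMMResult, theta, names) -> np.ndarray:
    s2_e, s2_l, s2_s = _unpack(theta, names)
    _, xtvx, _, _, _ = _crossprods_at(result, s2_e, s2_l, s2_s)
    return np.linalg.inv(xtvx)


def _neg2_reml_at(result: LMMResult, theta, names) -> float:
    s2_e, s2_l, s2_s = _unpack(theta, names)
    _, xtvx, xtvy, ytvy, logdet_v = _crossprods_at(result, s2_e, s2_l, s2_s)
    if not np.isfinite(logdet_v):
        return np.inf
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - beta @ xtvy
    return logdet_v + logdet_x + rss


def _vcov_theta(result: LMMResult, theta, names, h: float = 1e-4) -> np.ndarray | None:
    """Asymptotic covariance of the log variance parameters from the REML Hessian."""
    key = tuple(names)
    if key in result._vcov_cache:
        return result._vcov_cache[key]
    result._vcov_cache[key] = _vcov_theta_uncached(result, theta, names, h)
    return result._vcov_cache[key]


def _vcov_theta_uncached(result, theta, names, h: float) -> np.ndarray | None:
    k = len(theta)
    hess = np.zeros((k, k))
    f0 = _neg2_reml_at(result, theta, names)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            fpp = _neg2_reml_at(result, theta + ei + ej, names)
            fpm = _neg2_reml_at(result, theta + ei - ej, names)
            fmp = _neg2_reml_at(result, theta - ei + ej, names)
            fmm = _neg2_reml_at(result, theta - ei - ej, names)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    if not np.all(np.isfinite(hess)) or not np.isfinite(f0):
        return None
    # neg2 = -2 loglik, so information = 0.5 * hessian
    info = 0.5 * hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(cov) <= 0):
        return None
    return cov


def satterthwaite_df_scalar(result: LMMResult, contrast: np.ndarray) -> float | None:
    """Satterthwaite df for a single contrast l'beta; None if unavailable."""
    if result._X is None or result.sigma2_litter is None:
        return None
    theta, names = _theta_hat(result)
    vcov = _vcov_theta(result, theta, names)
    if vcov is None:
        return None
    l = np.asarray(contrast, dtype=float)

    def var_l(th):
        return float(l @ _cov_beta_at(result, th, names) @ l)

    h = 1e-4
    grad = np.zeros(len(theta))
    for i in range(len(theta)):
        e = np.zeros(len(theta))
        e[i] = h
        grad[i] = (var_l(theta + e) - var_l(theta - e)) / (2 * h)
    denom = float(grad @ vcov @ grad)
    if denom <= 0:
        return None
    v0 = var_l(theta)
    nu = 2.0 * v0 * v0 / denom
    if not np.isfinite(nu) or nu <= 0:
        return None
    return nu


def satterthwaite_df_multi(result: LMMResult, L: np.ndarray) -> float | None:
    """Denominator df for the F-test of L beta = 0 (eigen-contrast combination)."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = L.shape[0]
    if q == 1:
        return satterthwaite_df_scalar(result, L[0])
    M = L @ result.cov_beta @ L.T
    try:
        eigval, eigvec = np.linalg.eigh(M)
    except np.linalg.LinAlgError:
        return None
    nus = []
    for i in range(q):
        li = L.T @ eigvec[:, i]
        nu_i = satterthwaite_df_scalar(result, li)
        if nu_i is None:
            return None
        nus.append(nu_i)
    contrib = [nu / (nu - 2.0) for nu in nus if nu > 2.0]
    if not contrib:
        return None
    e_sum = float(np.sum(contrib))
    if e_sum <= q:
        return None
    return 2.0 * e_sum / (e_sum - q)
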