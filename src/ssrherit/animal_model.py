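"""REML animal models with a marker-inferred relatedness matrix.

The animal model treats each individual's additive genetic value
(breeding value) as a random effect whose covariance is proportional to
a relatedness matrix ``M``::

    y = X b + Z a + e,   Var(a) = M * Va,   Var(e) = I * Ve

With one record per individual ``Z = I`` and the phenotypic covariance
is ``V = Va*M + Ve*I``.  Narrow-sense heritability is
``h2 = Va / (Va + Ve)``.

Estimation is restricted maximum likelihood.  A single spectral
decomposition ``M = U diag(d) U'`` rotates the model so that ``V``
becomes diagonal in the ratio ``lambda = Va/Ve``; the REML
log-likelihood is profiled over ``lambda`` on a log grid and refined
with Brent's method.  Standard errors of the variance components come
from the inverse expected REML information, heritability confidence
intervals from the delta method (not truncated at 0, so a lower bound
may be negative), variance significance from a one-sided Z-test, and
fixed terms from incremental Wald F-tests with residual denominator
degrees of freedom.

Genetic covariances between traits are estimated with bivariate REML:
``Var(a) = G0 (x) M`` and ``Var(e) = R0 (x) I`` with 2x2 ``G0``/``R0``
kept positive definite through Cholesky parameterization, optimized
numerically from univariate starting values.  The G matrix assembles
univariate variances on the diagonal and pairwise covariances off it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import optimize, stats
from scipy.linalg import qr as scipy_qr

from ssrherit.relatedness import RelatednessMatrix

DEFAULT_FORMULA = (
    "C(transect) + C(elevation) + C(microhabitat) "
    "+ C(microhabitat):C(elevation) + C(microhabitat):C(transect)"
)

_LAMBDA_LO, _LAMBDA_HI = 1e-6, 1e6


class NotPositiveDefiniteError(ValueError):
    """Raised when the relatedness matrix is not PSD (run near_pd first)."""


@dataclass
class FixedDesign:
    """Treatment-coded fixed-effect design with per-term column bookkeeping."""

    matrix: np.ndarray
    columns: list[str]
    terms: dict[str, list[int]]
    dropped: list[str] = field(default_factory=list)
    ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def build_fixed_design(
    factors: pd.DataFrame, formula: str | None = None
) -> FixedDesign:
    """Build the fixed-effect design matrix from a factor table.

    The default formula uses transect (3 levels), elevation (2),
    microhabitat (2) and the microhabitat x elevation and microhabitat x
    transect interactions, treatment-coded with an intercept.  Columns
    made aliased by the data (e.g. a single-site subset) are dropped via
    pivoted QR and reported in ``dropped``.
    """
    if formula is None:
        formula = DEFAULT_FORMULA
    dm = dmatrix("1 + " + formula, factors, return_type="dataframe")
    x = np.asarray(dm, dtype=float)
    names = list(dm.columns)
    info = dm.design_info
    terms = {
        term_name: list(range(sl.start, sl.stop))
        for term_name, sl in info.term_name_slices.items()
    }
    # drop aliased columns, keeping earlier columns (intercept first)
    _, r, piv = scipy_qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in range(len(names)) if i not in keep]
    if dropped:
        warnings.warn(f"dropping aliased design columns: {dropped}")
        remap = {old: new for new, old in enumerate(keep)}
        x = x[:, keep]
        terms = {
            t: [remap[i] for i in cols if i in remap]
            for t, cols in terms.items()
        }
        names = [names[i] for i in keep]
    empty_terms = [t for t, cols in terms.items() if not cols]
    if empty_terms:
        warnings.warn(
            f"factor terms aliased into the intercept (single level or "
            f"rank-deficient): {empty_terms}"
        )
        dropped = dropped + empty_terms
    ids = list(factors.index.astype(str)) if factors.index is not None else None
    return FixedDesign(x, names, terms, dropped, ids)


@dataclass
class VarianceComponentFit:
    """Univariate REML fit: variance components, h2, tests, diagnostics."""

    trait: str
    va: float
    ve: float
    se_va: float
    se_ve: float
    cov_va_ve: float
    loglik: float
    lambda_hat: float
    h2: float
    h2_se: float
    h2_ci: tuple[float, float]
    z_p: float
    wald: pd.DataFrame
    n: int
    n_params: int
    converged: bool = True
    identifiable: bool = True
    message: str = ""
    beta: np.ndarray | None = None

    def summary_row(self) -> dict:
        return {
            "trait": self.trait,
            "h2": self.h2,
            "lowCI": self.h2_ci[0],
            "upCI": self.h2_ci[1],
            "Va": self.va,
            "Vr": self.ve,
            "p": self.z_p,
            "n": self.n,
        }


def heritability(va: float, ve: float) -> float:
    """Narrow-sense heritability ``Va / (Va + Ve)``."""
    if va < 0 or ve < 0:
        raise ValueError("variance components must be non-negative")
    total = va + ve
    if total == 0:
        raise ValueError("Va + Ve is zero; heritability undefined")
    return va / total


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, RelatednessMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def _as_design(x) -> tuple[np.ndarray, dict[str, list[int]], list[str]]:
    if isinstance(x, FixedDesign):
        return x.matrix, x.terms, x.columns
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    terms = {f"x{j}": [j] for j in range(x.shape[1])}
    return x, terms, list(terms)


def _profile_quantities(
    lam: float, d: np.ndarray, ystar: np.ndarray, xstar: np.ndarray
) -> tuple[float, np.ndarray, float, float, float]:
    """GLS at fixed lambda in the rotated basis.

    Returns (rss_w, beta, logdet_V, logdet_XtVinvX, sigma_e2_hat).
    """
    w = lam * d + 1.0
    xw = xstar / w[:, None]
    xtx = xstar.T @ xw
    xty = xw.T @ ystar
    beta = np.linalg.solve(xtx, xty)
    resid = ystar - xstar @ beta
    rss = float(resid @ (resid / w))
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    return rss, beta, float(np.log(w).sum()), logdet_xtx, rss / max(
        len(ystar) - xstar.shape[1], 1
    )


def _profile_reml_m2l(
    lam: float, d: np.ndarray, ystar: np.ndarray, xstar: np.ndarray
) -> float:
    """-2 * restricted log-likelihood profiled over sigma_e2, at fixed lambda."""
    n, p = xstar.shape
    rss, _, logdet_v, logdet_x, _ = _profile_quantities(lam, d, ystar, xstar)
    nm = n - p
    return (
        nm * np.log(rss / nm)
        + logdet_v
        + logdet_x
        + nm
        + nm * np.log(2.0 * np.pi)
    )


def _expected_information(
    va: float, ve: float, d: np.ndarray, xstar: np.ndarray
) -> np.ndarray:
    """Expected REML information for (Va, Ve): I_jk = tr(P V_j P V_k) / 2."""
    w = va * d + ve
    a = 1.0 / w
    xw = xstar * a[:, None]
    xtx_inv = np.linalg.inv(xstar.T @ xw)
    # P = diag(a) - Xw (X'AX)^-1 Xw'   (in the rotated basis, M = diag(d))
    b = xw @ xtx_inv @ xw.T
    p_mat = np.diag(a) - b
    pm = p_mat * d[None, :]  # P @ diag(d)
    i_aa = 0.5 * float(np.sum(pm * pm.T))
    i_ae = 0.5 * float(np.sum(pm * p_mat.T))
    i_ee = 0.5 * float(np.sum(p_mat * p_mat.T))
    return np.array([[i_aa, i_ae], [i_ae, i_ee]])


def reml_univariate(
    y: np.ndarray,
    X,
    M,
    trait: str = "trait",
    lambda_fixed: float | None = None,
    ci_level: float = 0.95,
    n_grid: int = 201,
) -> VarianceComponentFit:
    """Fit the univariate animal model by REML.

    ``y`` may contain NaN (listwise deletion); rows of ``X`` and ``M``
    are subset accordingly.  ``lambda_fixed`` pins the variance ratio
    ``Va/Ve`` (0 gives the pure fixed-effects GLS/OLS fit, used e.g. for
    classical ANOVA comparisons).
    """
    y = np.asarray(y, dtype=float).ravel()
    x_full, terms, colnames = _as_design(X)
    m_full = _as_matrix(M)
    if not (len(y) == x_full.shape[0] == m_full.shape[0]):
        raise ValueError("y, X and M must have aligned rows")
    mask = np.isfinite(y)
    y = y[mask]
    x = x_full[mask]
    m = m_full[np.ix_(mask, mask)]
    n = len(y)
    if n < x.shape[1] + 2:
        raise ValueError(f"too few complete cases ({n}) for {x.shape[1]} columns")
    if np.ptp(y) == 0:
        raise ValueError("constant response: trait has zero variance")

    off = m - np.diag(np.diag(m))
    if np.any(off >= 1.0 - 1e-10):
        raise ValueError(
            "relatedness matrix contains off-diagonal entries of 1: clonal "
            "replicates make it singular — keep one patch per genotype "
            "(clone filtering) before fitting"
        )
    d, u = np.linalg.eigh(0.5 * (m + m.T))
    if d[0] < -1e-6:
        raise NotPositiveDefiniteError(
            f"relatedness matrix has eigenvalue {d[0]:.3g} < 0; "
            "apply near_pd before fitting"
        )
    d = np.clip(d, 0.0, None)
    identifiable = (d.max() - d.min()) > 1e-8 * max(d.max(), 1.0)

    ystar = u.T @ y
    xstar = u.T @ x
    p = x.shape[1]
    nm = n - p

    if lambda_fixed is not None:
        lam_hat = float(lambda_fixed)
    elif not identifiable:
        lam_hat = 0.0
    else:
        grid = np.concatenate(
            [[0.0], np.geomspace(_LAMBDA_LO, _LAMBDA_HI, n_grid)]
        )
        vals = np.array([_profile_reml_m2l(l, d, ystar, xstar) for l in grid])
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if k == 0:
            lam_hat = 0.0
            if hi > 0:  # make sure the boundary really is the optimum
                res = optimize.minimize_scalar(
                    lambda t: _profile_reml_m2l(np.exp(t), d, ystar, xstar),
                    bounds=(np.log(_LAMBDA_LO), np.log(max(hi, _LAMBDA_LO * 10))),
                    method="bounded",
                    options={"xatol": 1e-10},
                )
                if res.fun < vals[k] - 1e-12:
                    lam_hat = float(np.exp(res.x))
        else:
            res = optimize.minimize_scalar(
                lambda t: _profile_reml_m2l(np.exp(t), d, ystar, xstar),
                bounds=(np.log(max(lo, _LAMBDA_LO / 10)), np.log(hi)),
                method="bounded",
                options={"xatol": 1e-12},
            )
            lam_hat = float(np.exp(res.x))
            if res.fun > vals[k]:
                lam_hat = float(grid[k])

    rss, beta, *_ = _profile_quantities(lam_hat, d, ystar, xstar)
    ve = rss / nm
    va = lam_hat * ve
    loglik = -0.5 * _profile_reml_m2l(lam_hat, d, ystar, xstar)

    info = _expected_information(va, ve, d, xstar)
    try:
        cov = np.linalg.inv(info)
        se_va = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_ve = float(np.sqrt(max(cov[1, 1], 0.0)))
        cov_ave = float(cov[0, 1])
        ci_ok = True
    except np.linalg.LinAlgError:
        se_va = se_ve = cov_ave = np.nan
        ci_ok = False

    if identifiable:
        h2 = heritability(va, ve)
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        total = va + ve
        grad = np.array([ve, -va]) / total**2
        h2_se = (
            float(np.sqrt(max(grad @ cov @ grad, 0.0))) if ci_ok else np.nan
        )
        h2_ci = (h2 - z * h2_se, h2 + z * h2_se)
        z_p = (
            0.5
            if va <= 0 or not np.isfinite(se_va) or se_va == 0
            else float(stats.norm.sf(va / se_va))
        )
    else:
        h2 = h2_se = np.nan
        h2_ci = (np.nan, np.nan)
        z_p = np.nan

    wald = _incremental_wald(lam_hat, d, ystar, xstar, terms, colnames, ve, nm)

    return VarianceComponentFit(
        trait=trait,
        va=va,
        ve=ve,
        se_va=se_va,
        se_ve=se_ve,
        cov_va_ve=cov_ave,
        loglik=loglik,
        lambda_hat=lam_hat,
        h2=h2,
        h2_se=h2_se,
        h2_ci=h2_ci,
        z_p=z_p,
        wald=wald,
        n=n,
        n_params=p,
        identifiable=identifiable,
        message="" if identifiable else "M is proportional to I; Va and Ve confounded",
        beta=beta,
    )


def _incremental_wald(
    lam: float,
    d: np.ndarray,
    ystar: np.ndarray,
    xstar: np.ndarray,
    terms: dict[str, list[int]],
    colnames: list[str],
    ve: float,
    ddf: int,
) -> pd.DataFrame:
    """Sequential (incremental) Wald F per fixed term at the estimated V."""
    w = np.sqrt(lam * d + 1.0)
    yt = ystar / w
    xt = xstar / w[:, None]
    rows = []
    cols_so_far: list[int] = []
    rss_prev = float(yt @ yt)
    for term, cols in terms.items():
        if not cols:
            rows.append(
                {"term": term, "df": 0, "F": np.nan, "p": np.nan, "note": "dropped"}
            )
            continue
        cols_so_far = cols_so_far + cols
        sub = xt[:, cols_so_far]
        beta, *_ = np.linalg.lstsq(sub, yt, rcond=None)
        rss = float(np.sum((yt - sub @ beta) ** 2))
        q = len(cols)
        f_stat = ((rss_prev - rss) / q) / ve
        p_val = float(stats.f.sf(f_stat, q, ddf)) if np.isfinite(f_stat) else np.nan
        rows.append({"term": term, "df": q, "F": f_stat, "p": p_val, "note": ""})
        rss_prev = rss
    return pd.DataFrame(rows)


def heritability_ci(
    fit: VarianceComponentFit, level: float = 0.95
) -> tuple[float, float]:
    """Delta-method CI of h2; bounds are not truncated at 0 or 1."""
    if not np.isfinite(fit.h2_se):
        raise ValueError("CI unavailable: singular information matrix")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (fit.h2 - z * fit.h2_se, fit.h2 + z * fit.h2_se)


def variance_z_test(fit: VarianceComponentFit) -> float:
    """One-sided Z-test p-value for Va > 0 (p = 0.5 at the Va = 0 boundary)."""
    return fit.z_p


def wald_f_tests(fit: VarianceComponentFit) -> pd.DataFrame:
    """Incremental Wald F-table of the fixed terms (computed at the fit)."""
    return fit.wald


# ---------------------------------------------------------------------------
# bivariate REML and the G matrix
# ---------------------------------------------------------------------------


@dataclass
class BivariateFit:
    """Bivariate REML fit for one trait pair."""

    traits: tuple[str, str]
    g0: np.ndarray
    r0: np.ndarray
    sigma_a12: float
    se_a12: float
    p_a12: float
    loglik: float
    n: int
    converged: bool
    message: str = ""

    @property
    def genetic_correlation(self) -> float:
        denom = np.sqrt(self.g0[0, 0] * self.g0[1, 1])
        return float(self.g0[0, 1] / denom) if denom > 0 else np.nan


def _chol_from_theta(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lg = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    lr = np.array([[np.exp(theta[3]), 0.0], [theta[4], np.exp(theta[5])]])
    return lg @ lg.T, lr @ lr.T


def _bivariate_m2l(
    g0: np.ndarray,
    r0: np.ndarray,
    d: np.ndarray,
    y1: np.ndarray,
    y2: np.ndarray,
    xstar: np.ndarray,
) -> float:
    """-2 restricted loglik of the 2-trait model in the rotated basis."""
    s11 = d * g0[0, 0] + r0[0, 0]
    s12 = d * g0[0, 1] + r0[0, 1]
    s22 = d * g0[1, 1] + r0[1, 1]
    det = s11 * s22 - s12**2
    if np.any(det <= 0) or np.any(s11 <= 0):
        return np.inf
    w11 = s22 / det
    w12 = -s12 / det
    w22 = s11 / det
    logdet_v = float(np.log(det).sum())
    p = xstar.shape[1]
    a11 = xstar.T @ (xstar * w11[:, None])
    a12 = xstar.T @ (xstar * w12[:, None])
    a22 = xstar.T @ (xstar * w22[:, None])
    xtvx = np.block([[a11, a12], [a12, a22]])
    u1 = xstar.T @ (w11 * y1 + w12 * y2)
    u2 = xstar.T @ (w12 * y1 + w22 * y2)
    u = np.concatenate([u1, u2])
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, u)
    yvy = float(w11 @ y1**2 + 2.0 * (w12 @ (y1 * y2)) + w22 @ y2**2)
    ypy = yvy - float(u @ beta)
    n2 = 2 * len(y1)
    return logdet_v + logdet_x + ypy + (n2 - 2 * p) * np.log(2.0 * np.pi)


def reml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    X,
    M,
    traits: tuple[str, str] = ("trait1", "trait2"),
) -> BivariateFit:
    """Estimate the additive genetic covariance of two traits by REML.

    Fits ``Var(a) = G0 (x) M``, ``Var(e) = R0 (x) I`` with 2x2 PSD
    ``G0``/``R0`` (Cholesky parameterization), started from univariate
    fits.  When the same trait vector is supplied twice the residual
    cross-covariance is not identifiable (``R0`` singular in the limit);
    this degenerate case is detected and the univariate decomposition is
    returned, whose analytic limit has ``sigma_a12`` equal to the
    univariate ``Va``.
    """
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    x_full, _, _ = _as_design(X)
    m_full = _as_matrix(M)
    mask = np.isfinite(y1) & np.isfinite(y2)
    y1c, y2c = y1[mask], y2[mask]
    x = x_full[mask]
    m = m_full[np.ix_(mask, mask)]
    n = len(y1c)

    if np.allclose(y1c, y2c):
        uni = reml_univariate(y1c, x, m, trait=traits[0])
        g0 = np.full((2, 2), uni.va)
        r0 = np.full((2, 2), uni.ve)
        return BivariateFit(
            traits, g0, r0, uni.va, uni.se_va,
            float(2.0 * stats.norm.sf(abs(uni.va / uni.se_va)))
            if uni.se_va > 0 else np.nan,
            uni.loglik, n, True,
            "identical traits: returned univariate decomposition",
        )

    d, u = np.linalg.eigh(0.5 * (m + m.T))
    if d[0] < -1e-6:
        raise NotPositiveDefiniteError(
            "relatedness matrix is not PSD; apply near_pd before fitting"
        )
    d = np.clip(d, 0.0, None)
    y1s, y2s = u.T @ y1c, u.T @ y2c
    xstar = u.T @ x

    fits = [
        reml_univariate(ys, x, m, trait=t)
        for ys, t in ((y1c, traits[0]), (y2c, traits[1]))
    ]
    floor = 1e-6 * float(np.var(y1c) + np.var(y2c))
    theta0 = np.array(
        [
            0.5 * np.log(max(fits[0].va, floor)),
            0.0,
            0.5 * np.log(max(fits[1].va, floor)),
            0.5 * np.log(max(fits[0].ve, floor)),
            0.0,
            0.5 * np.log(max(fits[1].ve, floor)),
        ]
    )

    def objective(theta: np.ndarray) -> float:
        g0, r0 = _chol_from_theta(theta)
        return _bivariate_m2l(g0, r0, d, y1s, y2s, xstar)

    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=[(-15.0, 15.0)] * 6,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(
            f"bivariate REML failed to converge: {res.message}; "
            f"best -2l = {res.fun:.6g}, |grad| = "
            f"{np.linalg.norm(getattr(res, 'jac', np.nan)):.3g}"
        )
    g0, r0 = _chol_from_theta(res.x)
    loglik = -0.5 * float(res.fun)

    # observed information on the natural scale (g11, g12, g22, r11, r12, r22)
    def m2l_natural(v: np.ndarray) -> float:
        g = np.array([[v[0], v[1]], [v[1], v[2]]])
        r = np.array([[v[3], v[4]], [v[4], v[5]]])
        return _bivariate_m2l(g, r, d, y1s, y2s, xstar)

    v0 = np.array([g0[0, 0], g0[0, 1], g0[1, 1], r0[0, 0], r0[0, 1], r0[1, 1]])
    se_a12 = np.nan
    try:
        h = _numerical_hessian(m2l_natural, v0)
        cov = 2.0 * np.linalg.inv(h)
        if cov[1, 1] > 0:
            se_a12 = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        pass
    sigma_a12 = float(g0[0, 1])
    p_a12 = (
        float(2.0 * stats.norm.sf(abs(sigma_a12) / se_a12))
        if np.isfinite(se_a12) and se_a12 > 0
        else np.nan
    )
    return BivariateFit(
        traits, g0, r0, sigma_a12, se_a12, p_a12, loglik, n,
        bool(res.success), str(res.message),
    )


def _numerical_hessian(fun, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = len(x0)
    h = np.maximum(np.abs(x0) * rel_step, 1e-8)
    hess = np.zeros((k, k))
    f0 = fun(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                fp = fun(x0 + ei)
                fm = fun(x0 - ei)
                hess[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
            else:
                fpp = fun(x0 + ei + ej)
                fpm = fun(x0 + ei - ej)
                fmp = fun(x0 - ei + ej)
                fmm = fun(x0 - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                    4.0 * h[i] * h[j]
                )
    return hess


@dataclass
class GMatrix:
    """Additive genetic (co)variance matrix across traits with significance."""

    traits: list[str]
    values: np.ndarray
    pvalues: np.ndarray
    univariate: dict[str, VarianceComponentFit]
    bivariate: dict[tuple[str, str], BivariateFit]

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("G matrix must be symmetric")
        if np.any(np.diag(self.values) < -1e-12):
            raise ValueError("negative additive variances on the diagonal")

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.pvalues < alpha

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.traits, columns=self.traits)


def g_matrix(
    traits_df: pd.DataFrame,
    factors: pd.DataFrame,
    M,
    trait_names: list[str] | None = None,
    formula: str | None = None,
) -> GMatrix:
    """Assemble the G matrix from univariate and pairwise bivariate fits.

    Diagonal entries are the univariate REML additive variances (with
    one-sided Z-test p-values); off-diagonals are pairwise bivariate
    additive covariances (two-sided Z-tests).  Each model uses its own
    complete cases and a design rebuilt on those rows.
    """
    names = list(trait_names) if trait_names is not None else list(traits_df.columns)
    if len(names) < 2:
        raise ValueError("G matrix needs at least two traits")
    k = len(names)
    values = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    uni: dict[str, VarianceComponentFit] = {}
    biv: dict[tuple[str, str], BivariateFit] = {}
    design = build_fixed_design(factors, formula)
    for i, t in enumerate(names):
        fit = reml_univariate(traits_df[t].to_numpy(), design, M, trait=t)
        uni[t] = fit
        values[i, i] = fit.va
        pvals[i, i] = fit.z_p
    for i in range(k):
        for j in range(i + 1, k):
            bf = reml_bivariate(
                traits_df[names[i]].to_numpy(),
                traits_df[names[j]].to_numpy(),
                design,
                M,
                traits=(names[i], names[j]),
            )
            biv[(names[i], names[j])] = bf
            values[i, j] = values[j, i] = bf.sigma_a12
            pvals[i, j] = pvals[j, i] = bf.p_a12
    return GMatrix(names, values, pvals, uni, biv)
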