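"""Raft size versus wind speed: generalized least squares with
moving-average correlated errors.

The response is log raft size; the predictor is wind speed.  Residuals from
consecutive observations on the same Julian day are serially correlated, so
the error covariance is block diagonal over days, each block a Toeplitz
MA(q) correlation matrix

    rho(h) = (theta_h + sum_i theta_i theta_{i+h}) / (1 + sum_i theta_i^2),
    h <= q;  rho(h) = 0 beyond the MA cutoff.

Given theta the regression coefficients and the scale are profiled out by
whitened least squares; theta itself is estimated by numerically maximising
the (restricted) log-likelihood over the invertibility region, reached
through the Jones (1980) reparameterisation.  An AR(q) correlation structure
is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular, toeplitz
from scipy.optimize import minimize
from scipy.stats import t as t_dist

__all__ = [
    "SizeModelFit",
    "SizeModelError",
    "ma_acf",
    "ma_correlation_matrix",
    "ar_correlation_matrix",
    "fit_gls_ma",
    "standardized_residuals",
]


class SizeModelError(RuntimeError):
    pass


@dataclass
class SizeModelFit:
    """Coefficients and diagnostics of the correlated-error raft-size model."""

    params: np.ndarray           # (intercept, wind slope)
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    conf_int: np.ndarray         # (2, 2): rows = coefficients, cols = lo/hi
    theta: np.ndarray            # MA (or AR) parameters
    sigma: float                 # residual standard error (marginal sd scale)
    log_likelihood: float
    aic: float
    bic: float
    method: str                  # "REML" or "ML"
    structure: str               # "ma" or "ar"
    nobs: int
    df_resid: int
    converged: bool
    resid_standardized: np.ndarray = field(repr=False, default=None)
    exog_names: tuple[str, ...] = ("Intercept", "Wind Speed")

    def residual_summary(self) -> dict[str, float]:
        """Min / Q1 / median / Q3 / max of the standardized residuals."""
        q = np.quantile(self.resid_standardized, [0.0, 0.25, 0.5, 0.75, 1.0])
        return dict(zip(["min", "q1", "med", "q3", "max"], q.tolist()))

    def summary(self) -> str:
        lines = [
            f"GLS with {self.structure.upper()}({len(self.theta)}) errors nested in day "
            f"({self.method})",
            f"AIC {self.aic:.1f}   BIC {self.bic:.1f}   logLik {self.log_likelihood:.1f}",
            "theta: " + "  ".join(f"{t:.3f}" for t in self.theta),
            f"{'Predictor':<12}{'Value':>9}{'Std.Err':>9}{'t':>8}{'p':>8}{'2.5%':>9}{'97.5%':>9}",
        ]
        for i, name in enumerate(self.exog_names):
            lines.append(
                f"{name:<12}{self.params[i]:>9.3f}{self.bse[i]:>9.3f}{self.tvalues[i]:>8.3f}"
                f"{self.pvalues[i]:>8.3f}{self.conf_int[i, 0]:>9.3f}{self.conf_int[i, 1]:>9.3f}"
            )
        rs = self.residual_summary()
        lines.append(
            "std. residuals: "
            + "  ".join(f"{rs[k]:.3f}" for k in ["min", "q1", "med", "q3", "max"])
        )
        lines.append(f"residual standard error {self.sigma:.3f}   n {self.nobs}   df {self.df_resid}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# correlation structures


def ma_acf(theta: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelations rho(0..max_lag) of an MA(q) process."""
    th = np.concatenate([[1.0], np.asarray(theta, dtype=float)])
    q = len(th) - 1
    denom = float(np.sum(th**2))
    rho = np.zeros(max_lag + 1)
    rho[0] = 1.0
    for h in range(1, max_lag + 1):
        if h <= q:
            rho[h] = float(np.sum(th[: q - h + 1] * th[h:])) / denom
    return rho


def _check_invertible(theta: np.ndarray) -> bool:
    th = np.asarray(theta, dtype=float)
    if not np.any(th):
        return True
    roots = np.roots(np.concatenate([th[::-1], [1.0]]))
    return bool(np.all(np.abs(roots) > 1.0 + 1e-10))


def ma_correlation_matrix(theta: np.ndarray, block_size: int) -> np.ndarray:
    """Toeplitz MA(q) correlation matrix for one within-day block.

    Requires theta inside the invertibility region (which also guarantees
    positive definiteness of the implied correlation).
    """
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    if not _check_invertible(theta):
        raise SizeModelError(f"MA parameters outside the invertibility region: {theta}")
    return toeplitz(ma_acf(theta, block_size - 1))


def ar_acf(phi: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelations of a stationary AR(p) process via Yule-Walker."""
    phi = np.asarray(phi, dtype=float)
    p = len(phi)
    if p == 0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    # solve for rho(1..p): rho(k) = sum_j phi_j rho(|k-j|)
    A = np.zeros((p, p))
    b = np.zeros(p)
    for k in range(1, p + 1):
        for j in range(1, p + 1):
            lag = abs(k - j)
            if lag == 0:
                b[k - 1] -= phi[j - 1]
            else:
                A[k - 1, lag - 1] += phi[j - 1]
        A[k - 1, k - 1] -= 1.0
    rho_1p = np.linalg.solve(A, b)
    rho = np.zeros(max_lag + 1)
    rho[0] = 1.0
    rho[1 : min(p, max_lag) + 1] = rho_1p[: min(p, max_lag)]
    for h in range(p + 1, max_lag + 1):
        rho[h] = float(np.dot(phi, rho[h - p : h][::-1]))
    return rho


def ar_correlation_matrix(phi: np.ndarray, block_size: int) -> np.ndarray:
    """Toeplitz AR(p) correlation matrix for one within-day block."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi):
        roots = np.roots(np.concatenate([-phi[::-1], [1.0]]))
        if not np.all(np.abs(roots) > 1.0 + 1e-10):
            raise SizeModelError(f"AR parameters outside the stationarity region: {phi}")
    return toeplitz(ar_acf(phi, block_size - 1))


# Jones (1980) reparameterisations: R^q -> invertible MA / stationary AR
# coefficients via partial-autocorrelation recursions.

def _transform_ma(u: np.ndarray) -> np.ndarray:
    new = np.tanh(u / 2.0)
    tmp = new.copy()
    for j in range(1, len(u)):
        b = new[j]
        for k in range(j):
            tmp[k] += b * new[j - k - 1]
        new[:j] = tmp[:j]
    return new


def _transform_ar(u: np.ndarray) -> np.ndarray:
    new = np.tanh(u / 2.0)
    tmp = new.copy()
    for j in range(1, len(u)):
        a = new[j]
        for k in range(j):
            tmp[k] -= a * new[j - k - 1]
        new[:j] = tmp[:j]
    return new


# ---------------------------------------------------------------------------
# fitting


def _prepare(data: pd.DataFrame):
    req = {"raft_size", "wind_speed", "julian_day"}
    missing = req - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = data.copy()
    sort_cols = ["julian_day"] + (["order"] if "order" in df.columns else [])
    df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    if (df["raft_size"] < 1).any():
        raise ValueError("raft sizes must be >= 1 (log-transformable)")
    y = np.log(df["raft_size"].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(df)), df["wind_speed"].to_numpy(dtype=float)])
    if np.unique(X[:, 1]).size < 2:
        raise SizeModelError("need at least 2 distinct wind speeds")
    blocks = [np.flatnonzero(df["julian_day"].to_numpy() == d)
              for d in pd.unique(df["julian_day"])]
    return y, X, blocks


def _profiled_loglik(theta, y, X, blocks, method, structure):
    """Profile out beta and sigma^2; return (loglik, beta, cov_unscaled, sigma2, whitened resid)."""
    n, p = X.shape
    corr_fn = ma_correlation_matrix if structure == "ma" else ar_correlation_matrix
    logdet = 0.0
    yw = np.empty_like(y)
    Xw = np.empty_like(X)
    # group blocks by size so each distinct size costs one Cholesky and one
    # batched triangular solve
    by_size: dict[int, list[np.ndarray]] = {}
    for idx in blocks:
        by_size.setdefault(len(idx), []).append(idx)
    for m, idx_list in by_size.items():
        L = np.linalg.cholesky(corr_fn(theta, m))
        logdet += 2.0 * float(np.sum(np.log(np.diag(L)))) * len(idx_list)
        cols = np.concatenate(idx_list)
        # stack blocks side by side: (m, n_blocks*(1+p)) right-hand side
        Yb = y[cols].reshape(len(idx_list), m).T
        Xb = X[cols].reshape(len(idx_list), m, p).transpose(1, 0, 2).reshape(m, -1)
        sol = solve_triangular(L, np.hstack([Yb, Xb]), lower=True)
        yw[cols] = sol[:, : len(idx_list)].T.ravel()
        Xw[cols] = sol[:, len(idx_list):].reshape(m, len(idx_list), p).transpose(1, 0, 2).reshape(-1, p)
    XtX = Xw.T @ Xw
    c, low = cho_factor(XtX)
    beta = cho_solve((c, low), Xw.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    if method == "REML":
        sigma2 = rss / (n - p)
        ll = (
            -0.5 * (n - p) * np.log(2.0 * np.pi * sigma2)
            - 0.5 * logdet
            - 0.5 * float(np.linalg.slogdet(XtX)[1])
            - 0.5 * (n - p)
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet - 0.5 * n
    cov_unscaled = cho_solve((c, low), np.eye(p))
    return float(ll), beta, cov_unscaled, sigma2, resid_w


def fit_gls_ma(
    data: pd.DataFrame,
    q: int = 4,
    method: str = "REML",
    structure: str = "ma",
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> SizeModelFit:
    """Fit log raft size ~ wind speed with MA(q) (or AR(q)) errors nested in
    Julian day.

    ``data`` needs columns ``raft_size, wind_speed, julian_day`` (and
    optionally ``order`` for the within-day sequence; input order is kept
    otherwise).  With ``q = 0`` the fit reduces exactly to ordinary least
    squares.
    """
    if method not in {"REML", "ML"}:
        raise ValueError(f"method must be REML or ML, got {method}")
    if structure not in {"ma", "ar"}:
        raise ValueError(f"structure must be 'ma' or 'ar', got {structure}")
    y, X, blocks = _prepare(data)
    n, p = X.shape

    if q == 0:
        theta_hat = np.zeros(0)
        ll, beta, cov_u, sigma2, resid_w = _profiled_loglik(theta_hat, y, X, blocks, method, structure)
        converged = True
    else:
        transform = _transform_ma if structure == "ma" else _transform_ar

        def objective(u):
            th = transform(u)
            try:
                ll, *_ = _profiled_loglik(th, y, X, blocks, method, structure)
            except (np.linalg.LinAlgError, SizeModelError):
                return 1e12
            return -ll

        rng = np.random.default_rng(seed)
        best = None
        for s in range(n_starts):
            u0 = np.zeros(q) if s == 0 else rng.normal(0.0, 0.5, size=q)
            res = minimize(objective, u0, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": tol, "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise SizeModelError("optimiser failed to converge; no usable restart")
        converged = bool(best.success)
        theta_hat = transform(best.x)
        ll, beta, cov_u, sigma2, resid_w = _profiled_loglik(theta_hat, y, X, blocks, method, structure)

    bse = np.sqrt(sigma2 * np.diag(cov_u))
    tvals = beta / bse
    df_resid = n - p
    pvals = 2.0 * t_dist.sf(np.abs(tvals), df_resid)
    tcrit = t_dist.ppf(0.975, df_resid)
    ci = np.column_stack([beta - tcrit * bse, beta + tcrit * bse])

    k = p + q + 1  # coefficients + correlation parameters + scale
    aic = 2.0 * k - 2.0 * ll
    n_eff = (n - p) if method == "REML" else n
    bic = k * np.log(n_eff) - 2.0 * ll

    return SizeModelFit(
        params=beta, bse=bse, tvalues=tvals, pvalues=pvals, conf_int=ci,
        theta=theta_hat, sigma=float(np.sqrt(sigma2)), log_likelihood=ll,
        aic=float(aic), bic=float(bic), method=method, structure=structure,
        nobs=n, df_resid=df_resid, converged=converged,
        resid_standardized=resid_w / np.sqrt(sigma2),
    )


def standardized_residuals(fit: SizeModelFit) -> tuple[np.ndarray, dict[str, float]]:
    """Whitened residuals (unit variance under the model) and their
    five-number summary."""
    return fit.resid_standardized, fit.residual_summary()
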