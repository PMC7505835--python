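"""Beta regression with a B-spline smooth in time since disturbance.

Retention benchmarks are fractions in (0, 1), so their dependence on time
since disturbance is modelled with a beta-distributed regression in the
mean-precision parameterization: ``y ~ Beta(mu * phi, (1 - mu) * phi)``
with ``logit(mu)`` linear in a design matrix and a single precision
``phi``.  The possibly non-linear effect of years since disturbance enters
as a B-spline basis whose degrees of freedom are selected from ``1..df_smooth``
by AIC with the usual parsimony rule — the smallest df within two AIC units
of the minimum (df = 1 reduces to the linear term); categorical covariates
(disturbance type, taxonomic group, ...) enter as dummy-coded fixed
effects.  The smooth's p-value is a likelihood-ratio test of the selected
model against the model without the years term, on the selected df.

Responses on the closed interval are first shrunk away from {0, 1} with the
standard ``(y * (n - 1) + 0.5) / n`` transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.special import digamma, expit, gammaln, logit
from scipy.stats import chi2

__all__ = [
    "squeeze_unit_interval",
    "beta_loglik",
    "bspline_basis",
    "fit_beta_gam",
    "BetaGamFit",
    "ConvergenceError",
    "RankDeficiencyError",
]


class ConvergenceError(RuntimeError):
    """Optimizer failed; message carries the iteration diagnostics."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; message names the aliased columns."""


def squeeze_unit_interval(y, n: int | None = None):
    """Map fractions in [0, 1] strictly inside (0, 1) via
    ``(y * (n - 1) + 0.5) / n``; order-preserving, fixed point at 0.5."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("y must lie in [0, 1]")
    if n is None:
        n = y.size
    if n < 2:
        raise ValueError("n must be >= 2")
    return (y * (n - 1) + 0.5) / n


def beta_loglik(y, mu, phi) -> float:
    """Beta log-likelihood in mean-precision form, summed over observations."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = float(phi)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("y must lie strictly in (0, 1); squeeze boundary values first")
    if np.any(mu <= 0) or np.any(mu >= 1) or phi <= 0:
        raise ValueError("mu must lie in (0, 1) and phi must be positive")
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
    return float(np.sum(ll))


def bspline_basis(x, df: int) -> np.ndarray:
    """B-spline basis with ``df`` columns (no intercept) over the range of x.

    Degree ``min(3, df)`` with interior knots at evenly spaced quantiles;
    the first basis function is dropped so the columns are identifiable next
    to an intercept.  ``df = 1`` yields a single column affine in x, i.e.
    the linear term.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("smooth covariate is constant")
    degree = min(3, df)
    n_interior = df - degree
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.empty(0)
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    # clip the right boundary into the half-open support of the last spline
    xe = np.clip(x, lo, hi)
    design = BSpline.design_matrix(xe, knots, degree, extrapolate=False).toarray()
    return design[:, 1:]


def _build_design(
    years: np.ndarray, covariates: pd.DataFrame | None, df: int | None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded covariates (+ optional years smooth basis)."""
    n = len(years)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.astype("category")
        dummies = pd.get_dummies(cov, drop_first=True, dtype=float)
        if dummies.shape[1]:
            blocks.append(dummies.to_numpy())
            names.extend(str(c) for c in dummies.columns)
    if df is not None:
        basis = bspline_basis(years, df)
        blocks.append(basis)
        names.extend(f"s(years).{j + 1}" for j in range(basis.shape[1]))
    X = np.hstack(blocks)
    _check_rank(X, names)
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns via QR with pivoting
        from scipy.linalg import qr as scipy_qr

        _, _, piv = scipy_qr(X, mode="economic", pivoting=True)
        aliased = [names[piv[j]] for j in range(rank, X.shape[1])]
        raise RankDeficiencyError(f"design matrix rank deficient; aliased columns: {aliased}")


def _fit_ml(y: np.ndarray, X: np.ndarray) -> dict:
    """Maximum-likelihood fit of the beta model with logit link.

    Parameters are (beta, log phi); optimized by L-BFGS-B with the analytic
    gradient, started from an OLS fit on the logit scale with a
    method-of-moments precision.
    """
    n, k = X.shape
    z = logit(y)
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    mu0 = expit(np.clip(X @ beta0, -30, 30))
    resid_var = float(np.var(z - X @ beta0)) if n > k else 0.1
    # on the logit scale Var(z) ~ 1 / (mu (1 - mu) phi) near the mean
    phi0 = float(np.clip(1.0 / max(resid_var * np.mean(mu0 * (1 - mu0)), 1e-8), 2.0, 1e4))
    theta0 = np.concatenate([beta0, [np.log(phi0)]])

    def unpack(theta):
        beta = theta[:-1]
        phi = np.exp(np.clip(theta[-1], -20, 20))
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return beta, phi, mu

    def negloglik(theta):
        _, phi, mu = unpack(theta)
        return -beta_loglik(y, mu, phi)

    def grad(theta):
        _, phi, mu = unpack(theta)
        ystar = np.log(y) - np.log1p(-y)
        mustar = digamma(mu * phi) - digamma((1 - mu) * phi)
        dl_dmu = phi * (ystar - mustar)
        dmu_deta = mu * (1 - mu)
        g_beta = X.T @ (dl_dmu * dmu_deta)
        dl_dphi = (
            digamma(phi)
            - mu * digamma(mu * phi)
            - (1 - mu) * digamma((1 - mu) * phi)
            + mu * np.log(y)
            + (1 - mu) * np.log1p(-y)
        )
        g_logphi = float(np.sum(dl_dphi)) * phi
        return -np.concatenate([g_beta, [g_logphi]])

    res = optimize.minimize(
        negloglik, theta0, jac=grad, method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-12}
    )
    if not res.success and res.status != 2:  # status 2: precision-limited line search
        raise ConvergenceError(
            f"beta regression did not converge: {res.message} "
            f"(nit={res.nit}, nfev={res.nfev}, |grad|={np.max(np.abs(res.jac)):.3g})"
        )
    theta = _newton_polish(negloglik, grad, res.x)
    beta, phi, mu = unpack(theta)
    cov = _observed_information_cov(grad, theta)
    return {
        "beta": beta,
        "phi": phi,
        "mu": mu,
        "loglik": beta_loglik(y, mu, phi),
        "n_params": len(theta),
        "cov": cov,
        "nit": int(res.nit),
    }


def _newton_polish(negloglik, grad, theta, max_iter: int = 50, gtol: float = 1e-10):
    """Newton refinement with step halving; makes the optimum independent of
    the (equivalent) parameterization the optimizer started from."""
    f = negloglik(theta)
    for _ in range(max_iter):
        g = grad(theta)
        if np.max(np.abs(g)) < gtol:
            break
        H = _finite_diff_hessian(grad, theta)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):  # halve until the objective does not increase
            candidate = theta - scale * step
            fc = negloglik(candidate)
            if fc <= f + 1e-12:
                theta, f = candidate, fc
                break
            scale *= 0.5
        else:
            break
    return theta


def _finite_diff_hessian(grad, theta, eps: float = 1e-6):
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = eps * max(1.0, abs(theta[j]))
        H[:, j] = (grad(theta + step) - grad(theta - step)) / (2 * step[j])
    return 0.5 * (H + H.T)


def _observed_information_cov(grad, theta_hat):
    """Covariance from the observed information (finite differences of the
    analytic gradient of the negative log-likelihood)."""
    H = _finite_diff_hessian(grad, theta_hat)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((len(theta_hat),) * 2, np.nan)


@dataclass(frozen=True)
class BetaGamFit:
    coefficients: pd.Series  # logit-scale coefficients, named
    se: pd.Series
    phi: float
    loglik: float
    edf: int  # AIC-selected df of the years smooth
    p_value: float  # LRT of the smooth against the no-years model
    pseudo_r2: float
    n_used: int
    aic_by_df: dict[int, float]
    fitted: np.ndarray
    y_squeezed: np.ndarray

    def report(self) -> dict:
        return {
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "phi": float(self.phi),
            "loglik": float(self.loglik),
            "edf": int(self.edf),
            "lrt_p_value": float(self.p_value),
            "pseudo_r2": float(self.pseudo_r2),
            "n_used": int(self.n_used),
            "aic_by_df": {str(k): float(v) for k, v in self.aic_by_df.items()},
        }


def fit_beta_gam(
    y,
    years,
    covariates: pd.DataFrame | None = None,
    df_smooth: int = 4,
) -> BetaGamFit:
    """Beta regression of a benchmark on years since disturbance.

    ``y`` is squeezed off the boundaries, the smooth's df is chosen from
    ``1..df_smooth`` by AIC, and the reported p-value compares the selected
    model with the no-years model by likelihood ratio (chi-squared on the
    selected df).
    """
    y = np.asarray(y, dtype=float)
    years = np.asarray(years, dtype=float)
    if y.shape != years.shape:
        raise ValueError("y and years must have the same length")
    if covariates is not None and len(covariates) != len(y):
        raise ValueError("covariates must have one row per observation")
    keep = np.isfinite(y) & np.isfinite(years)
    y, years = y[keep], years[keep]
    if covariates is not None:
        covariates = covariates.loc[np.asarray(keep)].reset_index(drop=True)
    n = len(y)
    if n < 10:
        raise ValueError(f"need >= 10 observations, got {n}")
    ys = squeeze_unit_interval(y, n)

    X0, _ = _build_design(years, covariates, df=None)
    null_fit = _fit_ml(ys, X0)

    fits = {}
    aic = {}
    for df in range(1, df_smooth + 1):
        X, names = _build_design(years, covariates, df=df)
        fit = _fit_ml(ys, X)
        fits[df] = (fit, names)
        aic[df] = 2 * fit["n_params"] - 2 * fit["loglik"]
    # parsimony rule: smallest df whose AIC is within 2 units of the minimum
    # (models closer than that are indistinguishable by AIC)
    best = min(aic.values())
    edf = min(d for d, a in aic.items() if a <= best + 2.0)
    fit, names = fits[edf]

    lr = 2.0 * (fit["loglik"] - null_fit["loglik"])
    p_value = float(chi2.sf(max(lr, 0.0), df=edf))

    eta_fit = logit(np.clip(fit["mu"], 1e-12, 1 - 1e-12))
    z = logit(ys)
    pseudo_r2 = float(np.corrcoef(eta_fit, z)[0, 1] ** 2) if np.ptp(eta_fit) > 0 else 0.0

    se = np.sqrt(np.clip(np.diag(fit["cov"])[:-1], 0, np.inf))
    return BetaGamFit(
        coefficients=pd.Series(fit["beta"], index=names),
        se=pd.Series(se, index=names),
        phi=fit["phi"],
        loglik=fit["loglik"],
        edf=edf,
        p_value=p_value,
        pseudo_r2=pseudo_r2,
        n_used=n,
        aic_by_df=aic,
        fitted=fit["mu"],
        y_squeezed=ys,
    )
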