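"""Spatially explicit regression of logit developmental-mode proportions.

Workflow: logit-transform the per-pixel proportions; screen candidate
predictor subsets for collinearity (pairwise |Pearson r| < 0.65 and
VIF < 3); build a Moran's I correlogram of the response to find the patch
size (the first zero-crossing distance of I(d)); assemble inverse-distance
spatial weights truncated at the patch size and row-standardised; and fit
the spatial lag model

    y = rho * W y + X beta + eps

by maximum likelihood, with the log-determinant ln|I - rho W| evaluated
exactly through the eigenvalues of W.  Model quality is reported as the
R-squared of the ordinary regression of observed on model-predicted values
(the reduced-form prediction (I - rho W)^{-1} X beta), plus ML AIC; the
significance of rho comes from a likelihood-ratio test against the rho = 0
(ordinary least squares) model.  All pairwise distances are haversine
great-circle distances with Earth radius 6371 km.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

EARTH_RADIUS_KM = 6371.0


def logit_transform(p, eps: float = 1e-3):
    """ln(p'/(1-p')) with p clipped into [eps, 1-eps]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    p = np.clip(p, eps, 1 - eps)
    out = np.log(p / (1 - p))
    return float(out) if out.ndim == 0 else out


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def pairwise_distances(lats, lons) -> np.ndarray:
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    return haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])


def variance_inflation_factors(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) of each column on the others (with intercept)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p == 1:
        return np.ones(1)
    vifs = np.empty(p)
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ coef
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        vifs[j] = np.inf if r2 >= 1 else 1.0 / (1.0 - r2)
    return vifs


def candidate_screen(X: pd.DataFrame, r_threshold: float = 0.65,
                     vif_threshold: float = 3.0,
                     max_size: int | None = None) -> list[tuple[str, ...]]:
    """Enumerate predictor subsets passing the collinearity screens.

    Keeps every non-empty subset whose pairwise absolute Pearson
    correlations are all below ``r_threshold`` and whose VIFs are all below
    ``vif_threshold``.  Constant columns are excluded with a warning.
    """
    cols = []
    for c in X.columns:
        if np.std(X[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"constant predictor {c!r} excluded", stacklevel=2)
        else:
            cols.append(c)
    if not cols:
        raise ValueError("no usable predictors")
    corr = X[cols].corr().abs()
    out = []
    top = len(cols) if max_size is None else min(max_size, len(cols))
    for size in range(1, top + 1):
        for subset in itertools.combinations(cols, size):
            if size > 1:
                sub = corr.loc[list(subset), list(subset)].to_numpy()
                if np.any(sub[np.triu_indices(size, 1)] >= r_threshold):
                    continue
                vifs = variance_inflation_factors(X[list(subset)].to_numpy(float))
                if np.any(vifs >= vif_threshold):
                    continue
            out.append(subset)
    return out


@dataclass
class Correlogram:
    """Moran's I per great-circle distance bin, with the patch size."""

    bin_centres: np.ndarray  # km
    morans_i: np.ndarray
    n_pairs: np.ndarray
    patch_size: float | None  # first positive-to-negative crossing, km


def morans_i(values, weights) -> float:
    """Moran's I of ``values`` under an arbitrary weight matrix."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    w = np.asarray(weights, dtype=float)
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("all-zero weight matrix")
    return float(z.size / s0 * (z @ w @ z) / (z @ z))


def morans_correlogram(values, lats, lons, bin_width_km: float = 50.0,
                       max_dist_km: float | None = None) -> Correlogram:
    """Binary-membership Moran's I correlogram over distance bins.

    The patch size is the linearly interpolated distance of the first
    positive-to-negative crossing of I(d); missing (None) when no sign
    change exists, with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 points for a correlogram")
    d = pairwise_distances(lats, lons)
    if max_dist_km is None:
        max_dist_km = float(d.max())
    edges = np.arange(0, max_dist_km + bin_width_km, bin_width_km)
    centres, eyes, npairs = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = ((d > lo) & (d <= hi)).astype(float)
        np.fill_diagonal(w, 0.0)
        pairs = int(w.sum())
        if pairs == 0:
            continue
        centres.append((lo + hi) / 2)
        eyes.append(morans_i(values, w))
        npairs.append(pairs)
    centres = np.array(centres)
    eyes = np.array(eyes)
    patch = None
    for k in range(len(eyes) - 1):
        if eyes[k] > 0 and eyes[k + 1] <= 0:
            frac = eyes[k] / (eyes[k] - eyes[k + 1])
            patch = float(centres[k] + frac * (centres[k + 1] - centres[k]))
            break
    if patch is None:
        warnings.warn("correlogram has no positive-to-negative crossing; "
                      "patch size undefined", stacklevel=2)
    return Correlogram(bin_centres=centres, morans_i=eyes,
                       n_pairs=np.array(npairs), patch_size=patch)


def build_weights(lats, lons, patch_size_km: float) -> np.ndarray:
    """Row-standardised inverse-distance weights truncated at the patch size.

    w_ij = 1/d_ij for 0 < d_ij <= patch size, else 0; each row is
    normalised to sum to 1 (isolated points keep an all-zero row, flagged
    with a warning).  Coincident points are an error.
    """
    if patch_size_km <= 0:
        raise ValueError("patch size must be positive")
    d = pairwise_distances(lats, lons)
    off = ~np.eye(d.shape[0], dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        raise ValueError(f"coincident points {i} and {j} (zero distance)")
    with np.errstate(divide="ignore"):
        w = np.where((d > 0) & (d <= patch_size_km), 1.0 / d, 0.0)
    rowsum = w.sum(axis=1, keepdims=True)
    isolated = rowsum.ravel() == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} point(s) have no neighbour "
                      "within the patch size", stacklevel=2)
    with np.errstate(invalid="ignore"):
        w = np.where(rowsum > 0, w / rowsum, 0.0)
    return w


@dataclass
class SarFit:
    """Maximum-likelihood spatial lag fit."""

    params: pd.DataFrame  # index: term; columns: estimate, std_error, z, p
    rho: float
    rho_se: float
    rho_p: float  # likelihood-ratio p-value of rho vs the OLS model
    loglik: float
    aic: float
    aic_ols: float  # AIC of the non-spatial counterpart
    r_squared: float  # from regression of observed on predicted
    predicted: np.ndarray
    terms: tuple


def _sar_loglik(rho: float, y, X, Wy, eigvals) -> tuple[float, np.ndarray, float]:
    """Concentrated log-likelihood at rho, with beta(rho) and sigma2(rho)."""
    n = y.size
    yr = y - rho * Wy
    beta, *_ = np.linalg.lstsq(X, yr, rcond=None)
    resid = yr - X @ beta
    sigma2 = float(resid @ resid) / n
    logdet = float(np.sum(np.log(np.abs(1.0 - rho * eigvals))))
    ll = -n / 2 * (np.log(2 * np.pi * sigma2) + 1) + logdet
    return float(ll), beta, sigma2


def fit_sar_lag(y, X, W, term_names=None, add_intercept: bool = True,
                rho_fixed: float | None = None) -> SarFit:
    """ML estimation of the spatial lag model y = rho W y + X beta + eps.

    ``W`` must be row-standardised (rows sum to 1 or 0).  Standard errors
    come from the numerical Hessian of the profile likelihood over
    (rho, beta); rho significance from the likelihood ratio against the
    rho = 0 (OLS) model.  With ``rho_fixed`` the autoregressive parameter
    is pinned (``rho_fixed=0`` reduces the fit exactly to OLS).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{k}" for k in range(p)]
    term_names = list(term_names)
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        term_names = ["intercept"] + term_names
    if n <= X.shape[1] + 2:
        raise ValueError("too few observations for the design")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    W = np.asarray(W, dtype=float)
    rowsums = W.sum(axis=1)
    if not np.all((np.abs(rowsums - 1) < 1e-8) | (np.abs(rowsums) < 1e-12)):
        raise ValueError("W must be row-standardised (rows sum to 1 or 0)")
    Wy = W @ y
    eigvals = np.linalg.eigvals(W)
    # feasible rho interval for a row-standardised W
    re = eigvals.real[np.abs(eigvals.imag) < 1e-9]
    lo = 1.0 / re.min() + 1e-6 if re.size and re.min() < 0 else -0.9999
    lo, hi = max(lo, -0.9999), 0.9999

    if rho_fixed is None:
        res = optimize.minimize_scalar(
            lambda r: -_sar_loglik(r, y, X, Wy, eigvals)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8})
        if not res.success:
            raise RuntimeError(f"SAR optimisation failed: {res.message}")
        rho = float(res.x)
    else:
        rho = float(rho_fixed)
    ll, beta, sigma2 = _sar_loglik(rho, y, X, Wy, eigvals)

    # OLS (rho = 0) counterpart for the likelihood-ratio test and AIC
    ll0, beta0, _ = _sar_loglik(0.0, y, X, Wy, np.zeros_like(eigvals))
    lr = 2 * (ll - ll0)
    rho_p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    k = X.shape[1] + 2  # betas + rho + sigma2
    aic = -2 * ll + 2 * k
    aic_ols = -2 * ll0 + 2 * (X.shape[1] + 1)

    # standard errors: numerical Hessian of the profile ll over (rho, beta)
    def negll(theta):
        r, b = theta[0], theta[1:]
        resid = y - r * Wy - X @ b
        s2 = float(resid @ resid) / n
        logdet = float(np.sum(np.log(np.abs(1.0 - r * eigvals))))
        return n / 2 * (np.log(2 * np.pi * s2) + 1) - logdet

    theta_hat = np.concatenate([[rho], beta])
    hess = _numerical_hessian(negll, theta_hat)
    try:
        cov = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(theta_hat.size, np.nan)
    se_rho, se_beta = ses[0], ses[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / se_beta
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    params = pd.DataFrame({"estimate": beta, "std_error": se_beta,
                           "z": zvals, "p": pvals}, index=term_names)

    predicted = np.linalg.solve(np.eye(n) - rho * W, X @ beta)
    r_squared = _obs_vs_pred_r2(y, predicted)
    return SarFit(params=params, rho=rho, rho_se=float(se_rho), rho_p=rho_p,
                  loglik=ll, aic=aic, aic_ols=aic_ols, r_squared=r_squared,
                  predicted=predicted, terms=tuple(term_names))


def _obs_vs_pred_r2(observed, predicted) -> float:
    """R^2 of the ordinary regression of observed on predicted values."""
    if np.std(predicted) == 0:
        return 0.0
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r**2)


def _numerical_hessian(f, x0, eps: float = 1e-5) -> np.ndarray:
    x0 = np.asarray(x0, dtype=float)
    k = x0.size
    h = eps * np.maximum(1.0, np.abs(x0))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def select_model(y, X: pd.DataFrame, W, subsets=None,
                 add_intercept: bool = True) -> tuple[SarFit, pd.DataFrame]:
    """Fit every admissible predictor subset; return the minimum-AIC fit.

    Ties in AIC (within 1e-9) are broken in favour of the smaller subset.
    Also returns the per-candidate AIC table (subset, aic, aic_ols).
    """
    if subsets is None:
        subsets = candidate_screen(X)
    if not subsets:
        raise ValueError("no admissible predictor subsets")
    fits, rows, failures = [], [], []
    for subset in subsets:
        try:
            fit = fit_sar_lag(y, X[list(subset)].to_numpy(float), W,
                              term_names=list(subset),
                              add_intercept=add_intercept)
        except Exception as exc:  # noqa: BLE001 - aggregate fit failures
            failures.append((subset, repr(exc)))
            continue
        fits.append((subset, fit))
        rows.append((subset, fit.aic, fit.aic_ols, fit.rho, fit.r_squared))
    if not fits:
        raise RuntimeError(f"all candidate fits failed: {failures}")
    table = pd.DataFrame(rows, columns=["subset", "aic", "aic_ols", "rho",
                                        "r_squared"])
    best = min(fits, key=lambda sf: (round(sf[1].aic / 1e-9) * 1e-9, len(sf[0])))
    return best[1], table
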