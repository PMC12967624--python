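"""Interspecific trait structure and developmental-mode probability.

Continuous life-history traits (sizes, growth ratios, developmental time,
fecundity) are log-transformed and z-scored; developmental mode and diet
enter as 0/1 dummies.  A PCA summarises the trait space; its leading axes
are regressed on taxon-mean environmental variables with a superfamily
random intercept (a coarse stand-in for phylogenetic structure, fitted by
ML through statsmodels MixedLM so that likelihood-ratio tests across models
differing in random structure are valid).  Developmental mode itself
(pelagic vs non-pelagic) is modelled with a weighted binomial mixed model:
a random-intercept logistic regression estimated by maximum likelihood with
Gauss-Hermite quadrature, with inverse-class-frequency observation weights
to offset the imbalance between the two modes.

R-squared components for mixed fits follow the variance-partition
(marginal/conditional) convention: r2_fixed = var(fixed)/total,
r2_group = var(group)/total, r2_total = their sum, where total also
includes the residual variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

CONTINUOUS_TRAITS = ("IS", "JS", "AS", "Gr1", "Gr2", "Gr3", "DT", "C")


def build_trait_matrix(records: pd.DataFrame,
                       continuous=CONTINUOUS_TRAITS,
                       categorical=("mode", "diet")) -> pd.DataFrame:
    """Natural-log + z-score continuous traits; one dummy per category level.

    All category levels are kept (suitable for PCA; regression designs
    should drop a reference level).  Raises on non-positive trait values or
    zero-variance columns, naming the offender.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 species")
    out = {}
    for trait in continuous:
        vals = records[trait].to_numpy(dtype=float)
        if np.any(vals <= 0) or np.any(~np.isfinite(vals)):
            bad = records.index[(vals <= 0) | ~np.isfinite(vals)][0]
            raise ValueError(f"non-positive or missing {trait} for species {bad!r}")
        logged = np.log(vals)
        sd = logged.std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero-variance trait {trait!r} cannot be scaled")
        out[trait] = (logged - logged.mean()) / sd
    for cat in categorical:
        for level in sorted(records[cat].unique()):
            out[f"{cat}_{level}"] = (records[cat] == level).astype(float).to_numpy()
    return pd.DataFrame(out, index=records.index)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # species x components
    loadings: pd.DataFrame  # variables x components
    variance_explained: np.ndarray  # fractions, summing to 1


def pca(matrix: pd.DataFrame) -> PcaResult:
    """Eigen-decomposition of the covariance of the prepared trait matrix."""
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("rank-0 matrix: no variance to decompose")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    comps = [f"PC{k + 1}" for k in range(s.size)]
    scores = pd.DataFrame(u * s, index=matrix.index, columns=comps)
    loadings = pd.DataFrame(vt.T, index=matrix.columns, columns=comps)
    return PcaResult(scores=scores, loadings=loadings,
                     variance_explained=var / var.sum())


@dataclass
class MixedFit:
    """Random-intercept linear mixed fit with LRT and variance-partition R^2."""

    params: pd.DataFrame  # estimate, std_error, t, p per fixed term
    group_var: float
    resid_var: float
    loglik: float
    loglik_nogroup: float
    lrt_stat: float
    lrt_p: float
    aic: float
    aic_nogroup: float
    r2_fixed: float
    r2_group: float
    r2_total: float


def lmm_fit(y, X: pd.DataFrame, groups) -> MixedFit:
    """ML random-intercept linear mixed model with an LRT for the group term.

    The LRT compares against the fixed-effects-only OLS model; its p-value
    uses chi-square df = 1 (conservative at the variance boundary).
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if np.unique(groups).size < 2:
        raise ValueError("need at least 2 groups")
    exog = sm.add_constant(X.to_numpy(dtype=float))
    names = ["intercept"] + list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        fit = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=False, method=method)
            except Exception:  # noqa: BLE001 - try the next optimiser
                continue
            if not np.isfinite(cand.llf):  # degenerate boundary artefact
                continue
            if fit is None or cand.llf > fit.llf + 1e-10:
                fit = cand
            if fit.converged and method == "lbfgs":
                break
        if fit is None:
            raise RuntimeError("mixed model did not converge (no finite fit)")
        if not fit.converged:
            # boundary fits (group variance ~ 0) often trip the flag; keep
            # the best finite-likelihood fit but say so
            warnings.warn("mixed model optimiser stopped at a boundary; "
                          "using best finite-likelihood fit", stacklevel=2)
        ols = sm.OLS(y, exog).fit()
    k = len(names)
    fe = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse[:k])
    tvals = fe / se
    pvals = 2 * stats.norm.sf(np.abs(tvals))
    params = pd.DataFrame({"estimate": fe, "std_error": se, "t": tvals,
                           "p": pvals}, index=names)
    group_var = float(np.asarray(fit.cov_re).ravel()[0])
    resid_var = float(fit.scale)
    ll, ll0 = float(fit.llf), float(ols.llf)
    lrt = max(0.0, 2 * (ll - ll0))
    var_f = float(np.var(exog @ fe))
    total = var_f + group_var + resid_var
    aic = -2 * ll + 2 * (k + 2)
    aic0 = -2 * ll0 + 2 * (k + 1)
    return MixedFit(params=params, group_var=group_var, resid_var=resid_var,
                    loglik=ll, loglik_nogroup=ll0, lrt_stat=lrt,
                    lrt_p=float(stats.chi2.sf(lrt, df=1)), aic=aic,
                    aic_nogroup=aic0, r2_fixed=var_f / total,
                    r2_group=group_var / total,
                    r2_total=(var_f + group_var) / total)


def class_weights(y) -> np.ndarray:
    """Inverse-class-frequency weights, normalised to sum to n.

    With k classes of sizes n_c, each member of class c gets n / (k n_c);
    a 50/50 binary split gives unit weights everywhere.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes present")
    n, k = y.size, classes.size
    lookup = {c: n / (k * m) for c, m in zip(classes, counts)}
    return np.array([lookup[v] for v in y], dtype=float)


@dataclass
class BinomialFit:
    """Weighted random-intercept logistic fit."""

    params: pd.DataFrame  # estimate, std_error, z, p per fixed term
    group_sd: float
    loglik: float
    loglik_nogroup: float
    lrt_stat: float
    lrt_p: float
    aic: float
    aic_nogroup: float
    accuracy_total: float  # percent
    accuracy_by_class: dict
    r_squared: float
    fitted_prob: np.ndarray
    group_effects: dict
    separation_flag: bool


def _glmm_loglik(beta, log_sigma, y, X, weights, group_idx, n_groups, gh_x, gh_w):
    """Weighted marginal log-likelihood via Gauss-Hermite quadrature."""
    sigma = np.exp(log_sigma)
    eta0 = X @ beta  # (n,)
    # nodes: u = sqrt(2) * sigma * x_q
    u = np.sqrt(2.0) * sigma * gh_x  # (q,)
    eta = eta0[:, None] + u[None, :]  # (n, q)
    # weighted Bernoulli log-density per observation and node
    ll_obs = weights[:, None] * (y[:, None] * eta - np.logaddexp(0.0, eta))
    # sum within groups -> (n_groups, q)
    ll_grp = np.zeros((n_groups, ll_obs.shape[1]))
    np.add.at(ll_grp, group_idx, ll_obs)
    return float(np.sum(special.logsumexp(ll_grp + np.log(gh_w)[None, :],
                                          axis=1) - 0.5 * np.log(np.pi)))


def binomial_glmm(y, X: pd.DataFrame, groups, weights=None,
                  n_quad: int = 21) -> BinomialFit:
    """Weighted logistic mixed model with a superfamily random intercept.

    Maximum likelihood via adaptive-free Gauss-Hermite quadrature
    (``n_quad`` nodes) over the random-intercept distribution.  Reports the
    LRT against the no-group weighted logistic model, AIC with and without
    the group term, overall and per-class accuracy at a 0.5 probability
    threshold (predictions include empirical-Bayes group intercepts), and
    the squared correlation between outcome and fitted probability.
    Complete separation is flagged, not raised.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("need both classes present")
    groups = np.asarray(groups)
    labels, group_idx = np.unique(groups, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    if weights is None:
        weights = np.ones_like(y)
    weights = np.asarray(weights, dtype=float)
    Xd = sm.add_constant(X.to_numpy(dtype=float))
    names = ["intercept"] + list(X.columns)

    # no-group weighted logistic fit: start values, LRT reference, AIC
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, Xd, family=sm.families.Binomial(),
                     freq_weights=weights).fit()
    ll0 = float(glm.llf)
    # complete separation: the fixed-effects fit reproduces y exactly
    separation = bool(np.all(np.abs(glm.fittedvalues - y) < 1e-6)
                      or np.any(np.abs(glm.params) > 30))

    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)  # physicists' form

    def negll(theta):
        return -_glmm_loglik(theta[:-1], theta[-1], y, Xd, weights,
                             group_idx, labels.size, gh_x, gh_w)

    theta0 = np.concatenate([np.asarray(glm.params), [np.log(0.5)]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(negll, theta0, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        if not res.success:  # one polish pass
            res = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-8,
                                             "maxiter": 4000})
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    ll = -float(res.fun)

    # standard errors from the numerical Hessian of the marginal likelihood
    from .spatial_regression import _numerical_hessian
    hess = _numerical_hessian(negll, res.x, eps=1e-4)
    try:
        cov = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(beta.size, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / ses
    params = pd.DataFrame({"estimate": beta, "std_error": ses, "z": zvals,
                           "p": 2 * stats.norm.sf(np.abs(zvals))}, index=names)

    # empirical-Bayes (posterior mode) group intercepts for prediction
    eta0 = Xd @ beta
    group_effects = {}
    u_hat = np.zeros(labels.size)
    for g in range(labels.size):
        sel = group_idx == g
        yg, wg, eg = y[sel], weights[sel], eta0[sel]

        def neg_post(u, yg=yg, wg=wg, eg=eg):
            pen = 0.5 * (u / sigma) ** 2 if sigma > 1e-8 else 0.0 if u == 0 else np.inf
            return -np.sum(wg * (yg * (eg + u) - np.logaddexp(0, eg + u))) + pen

        if sigma > 1e-8:
            u_hat[g] = optimize.minimize_scalar(neg_post,
                                                bounds=(-6 * sigma, 6 * sigma),
                                                method="bounded").x
        group_effects[labels[g]] = float(u_hat[g])
    prob = special.expit(eta0 + u_hat[group_idx])

    pred = (prob >= 0.5).astype(float)
    acc_total = float(np.mean(pred == y)) * 100
    acc_by_class = {int(c): float(np.mean(pred[y == c] == c)) * 100
                    for c in (0, 1)}
    lrt = max(0.0, 2 * (ll - ll0))
    k = len(names)
    return BinomialFit(params=params, group_sd=sigma, loglik=ll,
                       loglik_nogroup=ll0, lrt_stat=lrt,
                       lrt_p=float(stats.chi2.sf(lrt, df=1)),
                       aic=-2 * ll + 2 * (k + 1), aic_nogroup=-2 * ll0 + 2 * k,
                       accuracy_total=acc_total, accuracy_by_class=acc_by_class,
                       r_squared=float(np.corrcoef(y, prob)[0, 1] ** 2),
                       fitted_prob=prob, group_effects=group_effects,
                       separation_flag=separation)
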