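"""Binomial random-intercept GLMM fitted by maximum likelihood.

Trial-level adult learning is modelled as

    correct_ij ~ Bernoulli(p_ij),
    logit(p_ij) = x_ij' beta + u_i,      u_i ~ N(0, sigma_u^2),

with the marginal likelihood obtained by integrating the random
intercept out per individual using *adaptive* Gauss–Hermite quadrature:
the integrand is re-centred at each group's posterior mode and scaled by
its curvature before applying the Gauss–Hermite rule, so a modest
number of nodes (default 15; 1 node reproduces the Laplace
approximation) is accurate even for strongly informative groups.

A random-intercept + random-slope variant (slope on the standardised
trial index, unstructured 2x2 covariance, 2-D adaptive quadrature) is
provided solely to test the adequacy of the intercept-only structure.

Estimation is plain maximum likelihood — not REML — because fixed
effects are tested with likelihood-ratio tests, which require ML fits
of nested models on identical rows.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import stats as sps
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .stats import standardize

_SQRT2 = np.sqrt(2.0)
_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# data container and study design


@dataclasses.dataclass
class GLMMData:
    """Design matrix, response and grouping for one model fit.

    Rows are sorted by group. ``term_map`` names each testable fixed
    term and lists the design columns it owns (a factor may own several
    dummies); ``slope_col`` is the covariate carrying the optional
    random slope.
    """

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    term_map: dict[str, list[str]]
    slope_col: str | None = None

    def drop_term(self, term: str) -> "GLMMData":
        cols = self.term_map[term]
        new_map = {k: v for k, v in self.term_map.items() if k != term}
        return GLMMData(
            X=self.X.drop(columns=cols),
            y=self.y,
            groups=self.groups,
            term_map=new_map,
            slope_col=self.slope_col,
        )


def build_study_design(
    adult_trials: pd.DataFrame,
    mean_elo: Mapping[str, float],
    n_females: Mapping[str, int],
    cohort: Mapping[str, str],
) -> GLMMData:
    """Assemble the trial-level design for the adult learning model.

    The outcome of trial 1 becomes the ``first_choice`` covariate and
    its row is dropped, leaving trials 2–100 as the response rows.
    Trial index and mean Elo-rating are converted to z-scores over the
    analysis rows to aid convergence. Reference levels: 2 females,
    cohort I.
    """
    df = adult_trials[adult_trials["phase"] == "adult"].copy()
    first = df[df["trial"] == 1].set_index("individual")["correct"]
    df = df[df["trial"] >= 2].copy()
    missing = [i for i in df["individual"].unique() if i not in first.index]
    if missing:
        raise ValueError(f"individuals missing trial 1: {missing}")
    df["first_choice"] = df["individual"].map(first).astype(float)
    df["elo"] = df["individual"].map(dict(mean_elo))
    if df["elo"].isna().any():
        raise ValueError("individual without a mean Elo-rating")
    df["females"] = df["individual"].map(dict(n_females))
    df["cohort"] = df["individual"].map(dict(cohort))
    if df[["females", "cohort"]].isna().any().any():
        raise ValueError("individual without housing covariates")
    if not set(df["females"].unique()) <= {2, 4}:
        raise ValueError("n_females must be 2 or 4")

    df = df.sort_values(["individual", "trial"], kind="stable").reset_index(drop=True)
    trial_z = standardize(df["trial"].to_numpy(float))
    elo_z = standardize(df["elo"].to_numpy(float))
    X = pd.DataFrame(
        {
            "const": 1.0,
            "trial_z": trial_z,
            "elo_z": elo_z,
            "trial_z:elo_z": trial_z * elo_z,
            "females_4": (df["females"] == 4).astype(float),
            "cohort_II": (df["cohort"] == "II").astype(float),
            "first_choice": df["first_choice"].to_numpy(float),
        }
    )
    for col in ("females_4", "cohort_II"):
        if X[col].nunique() < 2:
            warnings.warn(f"factor column {col} is constant on these rows")
    term_map = {
        "trial": ["trial_z"],
        "elo": ["elo_z"],
        "trial:elo": ["trial_z:elo_z"],
        "females": ["females_4"],
        "cohort": ["cohort_II"],
        "first_choice": ["first_choice"],
    }
    return GLMMData(
        X=X,
        y=df["correct"].to_numpy(float),
        groups=df["individual"].to_numpy(),
        term_map=term_map,
        slope_col="trial_z",
    )


# ---------------------------------------------------------------------------
# fits and test results


@dataclasses.dataclass
class GLMMFit:
    estimates: pd.Series  # fixed effects
    se: pd.Series
    sigma_u: float  # random-intercept SD
    loglik: float
    converged: bool
    quad_points: int
    n_obs: int
    n_groups: int
    n_params: int
    term_map: dict[str, list[str]]
    random_structure: str = "intercept"  # "intercept" | "intercept+slope" | "none"
    slope_sd: float | None = None
    re_corr: float | None = None

    def fixed_effects_table(self) -> pd.DataFrame:
        """Estimates, SEs, odds ratios and Wald 95% bounds (both scales)."""
        est, se = self.estimates, self.se
        lo, hi = est - 1.96 * se, est + 1.96 * se
        return pd.DataFrame(
            {
                "estimate": est,
                "se": se,
                "or": np.exp(est),
                "link_lo": lo,
                "link_hi": hi,
                "or_lo": np.exp(lo),
                "or_hi": np.exp(hi),
            }
        )


@dataclasses.dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# marginal log-likelihood, random intercept (1-D adaptive GH)


def _group_starts(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start offsets and sizes of contiguous group blocks (rows pre-sorted)."""
    change = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    counts = np.diff(np.r_[change, len(groups)])
    return change, counts


def _bernoulli_loglik_rows(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def _modes_intercept(
    eta0: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    counts: np.ndarray,
    sigma: float,
    u0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and curvature of each group's random intercept.

    Newton iterations on the (strictly concave) joint log-density;
    returns modes and the negative Hessian diagonal at the modes.
    """
    n_groups = len(starts)
    u = np.zeros(n_groups) if u0 is None else u0.copy()
    inv_var = 1.0 / sigma**2
    for _ in range(100):
        eta = eta0 + np.repeat(u, counts)
        p = expit(eta)
        score = np.add.reduceat(y - p, starts) - u * inv_var
        neg_hess = np.add.reduceat(p * (1 - p), starts) + inv_var
        step = score / neg_hess
        np.clip(step, -5.0, 5.0, out=step)
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + np.repeat(u, counts)
    p = expit(eta)
    neg_hess = np.add.reduceat(p * (1 - p), starts) + inv_var
    return u, neg_hess


def marginal_loglik_intercept(
    beta: np.ndarray,
    sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    counts: np.ndarray,
    quad_points: int = 15,
) -> float:
    """Marginal log-likelihood with the intercept integrated out per group."""
    eta0 = X @ beta
    if sigma < 1e-8:
        return float(_bernoulli_loglik_rows(eta0, y).sum())
    u_hat, neg_hess = _modes_intercept(eta0, y, starts, counts, sigma)
    tau = 1.0 / np.sqrt(neg_hess)
    z, w = hermgauss(quad_points)
    log_w = np.log(w)
    log_terms = np.empty((quad_points, len(starts)))
    for k in range(quad_points):
        u_k = u_hat + _SQRT2 * tau * z[k]
        eta = eta0 + np.repeat(u_k, counts)
        g = np.add.reduceat(_bernoulli_loglik_rows(eta, y), starts)
        g += -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * (u_k / sigma) ** 2
        log_terms[k] = log_w[k] + z[k] ** 2 + g
    log_lik_groups = np.log(_SQRT2 * tau) + logsumexp(log_terms, axis=0)
    return float(log_lik_groups.sum())


# ---------------------------------------------------------------------------
# marginal log-likelihood, intercept + slope (2-D adaptive GH)


def _chol_from_theta(theta: np.ndarray) -> np.ndarray:
    """Unconstrained (log-Cholesky) parameters -> lower Cholesky factor."""
    return np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])


def _modes_slope(
    eta0: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    starts: np.ndarray,
    counts: np.ndarray,
    prec: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """2-D posterior modes and negative Hessians (n_groups, 2, 2)."""
    n_groups = len(starts)
    u = np.zeros((n_groups, 2))
    for _ in range(100):
        eta = eta0 + np.repeat(u[:, 0], counts) + np.repeat(u[:, 1], counts) * s
        p = expit(eta)
        r = y - p
        w = p * (1 - p)
        g0 = np.add.reduceat(r, starts)
        g1 = np.add.reduceat(r * s, starts)
        score = np.stack([g0, g1], axis=1) - u @ prec
        h00 = np.add.reduceat(w, starts) + prec[0, 0]
        h01 = np.add.reduceat(w * s, starts) + prec[0, 1]
        h11 = np.add.reduceat(w * s * s, starts) + prec[1, 1]
        det = h00 * h11 - h01 * h01
        step0 = (h11 * score[:, 0] - h01 * score[:, 1]) / det
        step1 = (h00 * score[:, 1] - h01 * score[:, 0]) / det
        step = np.stack([step0, step1], axis=1)
        np.clip(step, -5.0, 5.0, out=step)
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + np.repeat(u[:, 0], counts) + np.repeat(u[:, 1], counts) * s
    p = expit(eta)
    w = p * (1 - p)
    h00 = np.add.reduceat(w, starts) + prec[0, 0]
    h01 = np.add.reduceat(w * s, starts) + prec[0, 1]
    h11 = np.add.reduceat(w * s * s, starts) + prec[1, 1]
    neg_hess = np.empty((n_groups, 2, 2))
    neg_hess[:, 0, 0] = h00
    neg_hess[:, 0, 1] = neg_hess[:, 1, 0] = h01
    neg_hess[:, 1, 1] = h11
    return u, neg_hess


def marginal_loglik_slope(
    beta: np.ndarray,
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    starts: np.ndarray,
    counts: np.ndarray,
    quad_points: int = 9,
) -> float:
    """Marginal log-likelihood with correlated intercept+slope integrated out."""
    # keep the optimizer away from numerically degenerate covariances
    theta = np.clip(theta, [-8.0, -30.0, -8.0], [4.0, 30.0, 4.0])
    L = _chol_from_theta(theta)
    cov = L @ L.T
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        return -1e10
    _, logdet_cov = np.linalg.slogdet(cov)
    eta0 = X @ beta
    u_hat, neg_hess = _modes_slope(eta0, y, s, starts, counts, prec)
    n_groups = len(starts)
    # scale matrix A_j = chol(neg_hess^{-1}): nodes u = u_hat + sqrt(2) A z
    A = np.linalg.cholesky(np.linalg.inv(neg_hess))
    log_det_A = np.log(A[:, 0, 0] * A[:, 1, 1])
    z, w = hermgauss(quad_points)
    log_w = np.log(w)
    n_nodes = quad_points * quad_points
    log_terms = np.empty((n_nodes, n_groups))
    k = 0
    for k1 in range(quad_points):
        for k2 in range(quad_points):
            zvec = np.array([z[k1], z[k2]])
            offs = _SQRT2 * (A @ zvec)  # (n_groups, 2)
            u_k = u_hat + offs
            eta = eta0 + np.repeat(u_k[:, 0], counts) + np.repeat(u_k[:, 1], counts) * s
            g = np.add.reduceat(_bernoulli_loglik_rows(eta, y), starts)
            quad_form = np.einsum("gi,ij,gj->g", u_k, prec, u_k)
            g += -_LOG_2PI - 0.5 * logdet_cov - 0.5 * quad_form
            log_terms[k] = log_w[k1] + log_w[k2] + z[k1] ** 2 + z[k2] ** 2 + g
            k += 1
    log_lik_groups = np.log(2.0) + log_det_A + logsumexp(log_terms, axis=0)
    return float(log_lik_groups.sum())


# ---------------------------------------------------------------------------
# fitting


def _sorted_by_group(data: GLMMData):
    groups = np.asarray(data.groups)
    order = np.argsort(groups, kind="stable")
    X = data.X.to_numpy(float)[order]
    y = np.asarray(data.y, float)[order]
    g = groups[order]
    starts, counts = _group_starts(g)
    return X, y, g, starts, counts, order


def _start_values(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plain logistic-regression start values (IRLS via statsmodels)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
            beta = np.asarray(res.params, float)
            if np.all(np.isfinite(beta)) and np.max(np.abs(beta)) < 10:
                return beta
        except Exception:
            pass
    return np.zeros(X.shape[1])


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    hs = h * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = hs[i]
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return H


def fit_binomial_glmm(
    data: GLMMData,
    quad_points: int = 15,
    random_structure: str = "intercept",
    fix_sigma: float | None = None,
) -> GLMMFit:
    """Maximum-likelihood fit of the binomial mixed model.

    Parameters
    ----------
    data
        Design, response and grouping (see :func:`build_study_design`).
    quad_points
        Adaptive Gauss–Hermite order per dimension. 1 is the Laplace
        approximation.
    random_structure
        ``"intercept"`` (default), ``"intercept+slope"`` (adds a
        correlated random slope on ``data.slope_col``), or ``"none"``
        (ordinary logistic regression — the sigma=0 boundary).
    fix_sigma
        Fix the random-intercept SD instead of estimating it
        (``fix_sigma=0`` is equivalent to ``random_structure="none"``).
    """
    X, y, g, starts, counts, _ = _sorted_by_group(data)
    n_obs, p = X.shape
    n_groups = len(starts)
    if n_groups < 2 and random_structure != "none":
        raise ValueError("need >= 2 groups for a random effect")
    cols = list(data.X.columns)
    beta0 = _start_values(X, y)

    if fix_sigma is not None and fix_sigma == 0.0:
        random_structure = "none"

    if random_structure == "none":

        def obj(params):
            return -float(_bernoulli_loglik_rows(X @ params, y).sum())

        res = minimize(obj, beta0, method="L-BFGS-B", options={"ftol": 1e-12, "gtol": 1e-9})
        H = _numerical_hessian(obj, res.x)
        se = _safe_se(H, p)
        return GLMMFit(
            estimates=pd.Series(res.x, index=cols),
            se=pd.Series(se[:p], index=cols),
            sigma_u=0.0,
            loglik=-float(res.fun),
            converged=bool(res.success),
            quad_points=quad_points,
            n_obs=n_obs,
            n_groups=n_groups,
            n_params=p,
            term_map=dict(data.term_map),
            random_structure="none",
        )

    if random_structure == "intercept":
        if fix_sigma is not None:

            def obj(params):
                return -marginal_loglik_intercept(
                    params, fix_sigma, X, y, starts, counts, quad_points
                )

            res = minimize(obj, beta0, method="L-BFGS-B", options={"ftol": 1e-12, "gtol": 1e-9})
            H = _numerical_hessian(obj, res.x)
            se = _safe_se(H, p)
            return GLMMFit(
                estimates=pd.Series(res.x, index=cols),
                se=pd.Series(se[:p], index=cols),
                sigma_u=float(fix_sigma),
                loglik=-float(res.fun),
                converged=bool(res.success),
                quad_points=quad_points,
                n_obs=n_obs,
                n_groups=n_groups,
                n_params=p,
                term_map=dict(data.term_map),
                random_structure="intercept",
            )

        def obj(params):
            return -marginal_loglik_intercept(
                params[:p], params[p], X, y, starts, counts, quad_points
            )

        x0 = np.r_[beta0, 0.5]
        bounds = [(None, None)] * p + [(1e-8, None)]
        res = minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-9}
        )
        # the profile in sigma can be locally flat near the boundary; probe a
        # sigma grid at the current beta and restart if anything beats it
        for _ in range(2):
            probes = [np.r_[res.x[:p], s_] for s_ in (0.05, 0.1, 0.2, 0.4, 0.8)]
            vals = [obj(q) for q in probes]
            best = int(np.argmin(vals))
            if vals[best] < res.fun - 1e-7:
                res = minimize(
                    obj, probes[best], method="L-BFGS-B", bounds=bounds,
                    options={"ftol": 1e-12, "gtol": 1e-9},
                )
            else:
                break
        H = _numerical_hessian(obj, res.x)
        se = _safe_se(H, p + 1)
        return GLMMFit(
            estimates=pd.Series(res.x[:p], index=cols),
            se=pd.Series(se[:p], index=cols),
            sigma_u=float(res.x[p]),
            loglik=-float(res.fun),
            converged=bool(res.success),
            quad_points=quad_points,
            n_obs=n_obs,
            n_groups=n_groups,
            n_params=p + 1,
            term_map=dict(data.term_map),
            random_structure="intercept",
        )

    if random_structure == "intercept+slope":
        if data.slope_col is None:
            raise ValueError("data.slope_col required for a random slope")
        s = data.X[data.slope_col].to_numpy(float)[np.argsort(np.asarray(data.groups), kind="stable")]
        q2 = min(quad_points, 9)  # product grid; 9^2 nodes is ample

        def obj(params):
            return -marginal_loglik_slope(
                params[:p], params[p:], X, y, s, starts, counts, q2
            )

        # warm start from the intercept-only fit
        base = fit_binomial_glmm(data, quad_points=quad_points, random_structure="intercept")
        sig0 = max(base.sigma_u, 0.05)
        x0 = np.r_[base.estimates.to_numpy(), np.log(sig0), 0.0, np.log(0.05)]
        res = minimize(
            obj, x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-10},
        )
        # a gradient-based pass from the simplex optimum polishes convergence
        res = minimize(obj, res.x, method="L-BFGS-B", options={"ftol": 1e-12, "gtol": 1e-9})
        L = _chol_from_theta(res.x[p:])
        cov = L @ L.T
        H = _numerical_hessian(obj, res.x)
        se = _safe_se(H, p + 3)
        return GLMMFit(
            estimates=pd.Series(res.x[:p], index=cols),
            se=pd.Series(se[:p], index=cols),
            sigma_u=float(np.sqrt(cov[0, 0])),
            loglik=-float(res.fun),
            converged=bool(res.success),
            quad_points=q2,
            n_obs=n_obs,
            n_groups=n_groups,
            n_params=p + 3,
            term_map=dict(data.term_map),
            random_structure="intercept+slope",
            slope_sd=float(np.sqrt(cov[1, 1])),
            re_corr=float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])),
        )

    raise ValueError(f"unknown random_structure {random_structure!r}")


def _safe_se(H: np.ndarray, n: int) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


# ---------------------------------------------------------------------------
# likelihood-ratio machinery


def likelihood_ratio_test(full: GLMMFit, reduced: GLMMFit) -> LRTResult:
    """LRT of nested fits on identical rows; df = parameter-count difference."""
    if full.n_obs != reduced.n_obs or full.n_groups != reduced.n_groups:
        raise ValueError("fits are not on identical rows")
    if full.n_params <= reduced.n_params:
        raise ValueError("`full` must have more parameters than `reduced`")
    if not set(reduced.estimates.index) <= set(full.estimates.index):
        raise ValueError("reduced model terms are not a subset of the full model")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < -1e-4:
        raise ValueError(f"full model log-likelihood below reduced ({chi2/2:.6f}); not nested or not converged")
    chi2 = max(chi2, 0.0)
    df = full.n_params - reduced.n_params
    return LRTResult(chi2=float(chi2), df=df, p=float(sps.chi2.sf(chi2, df)))


def _droppable_terms(term_map: dict[str, list[str]]) -> list[str]:
    """Terms not protected by a retained interaction (a:b protects a and b)."""
    protected: set[str] = set()
    for term in term_map:
        if ":" in term:
            protected.update(term.split(":"))
    return [t for t in term_map if t not in protected]


def drop_term_lrts(
    data: GLMMData,
    quad_points: int = 15,
    full_fit: GLMMFit | None = None,
) -> pd.DataFrame:
    """Single-term deletion LRTs against the full model."""
    full_fit = full_fit or fit_binomial_glmm(data, quad_points=quad_points)
    rows = []
    for term in _droppable_terms(data.term_map):
        reduced = fit_binomial_glmm(data.drop_term(term), quad_points=quad_points)
        lrt = likelihood_ratio_test(full_fit, reduced)
        rows.append({"term": term, "chi2": lrt.chi2, "df": lrt.df, "p": lrt.p})
    return pd.DataFrame(rows)


def minimum_adequate_model(
    data: GLMMData,
    quad_points: int = 15,
    alpha: float = 0.05,
) -> tuple[GLMMFit, GLMMData, pd.DataFrame]:
    """Backward elimination of non-significant fixed terms by LRT.

    At each step the droppable term (never one inside a retained
    interaction) with the largest p-value above ``alpha`` is removed;
    elimination stops when every remaining droppable term is
    significant. Returns the final fit, its data, and the elimination
    history.
    """
    current = data
    fit = fit_binomial_glmm(current, quad_points=quad_points)
    history = []
    while True:
        lrts = drop_term_lrts(current, quad_points=quad_points, full_fit=fit)
        candidates = lrts[lrts["p"] > alpha]
        if candidates.empty:
            break
        worst = candidates.loc[candidates["p"].idxmax()]
        history.append(dict(worst))
        current = current.drop_term(str(worst["term"]))
        fit = fit_binomial_glmm(current, quad_points=quad_points)
    return fit, current, pd.DataFrame(history)


def compare_random_structures(data: GLMMData, quad_points: int = 15) -> LRTResult:
    """LRT of random-intercept-only vs correlated intercept+slope.

    df = 2 (slope variance + intercept–slope covariance); the boundary
    correction is deliberately ignored and a plain chi-square reference
    used.
    """
    intercept = fit_binomial_glmm(data, quad_points=quad_points, random_structure="intercept")
    slope = fit_binomial_glmm(
        data, quad_points=quad_points, random_structure="intercept+slope"
    )
    chi2 = max(0.0, 2.0 * (slope.loglik - intercept.loglik))
    return LRTResult(chi2=float(chi2), df=2, p=float(sps.chi2.sf(chi2, 2)))
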