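"""Group-level inference on gender differences in guilt sensitivity.

Three complementary analyses, always run per country:

* a random-intercept mixed-effects logistic regression of every choice on
  Reward, Guilt, Inequity, Gender (men = 1) and Gender x Guilt, with a
  Gaussian per-participant intercept integrated out by Gauss-Hermite
  quadrature — the Gender x Guilt fixed effect is the cooperation-level
  test of a gender gap in guilt aversion;
* a Lasso regression of the per-participant guilt coefficient beta(Guilt)
  on gender, Big Five and socioeconomic covariates (9 predictors), and a
  second specification adding the eight gender x covariate interactions
  (17 predictors), with the penalty chosen by ten-fold cross-validation;
* an ordinary-least-squares fit of the same design matrices as a
  collinearity-sensitive cross-check.

The Lasso coordinate-descent solver and the cross-validation scaffolding
come from scikit-learn; standardization, the lambda grid, the lambda rule
(CV-minimum or one-standard-error) and back-transformation to the original
covariate scale are handled here.  OLS goes through statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "MixedLogitResult",
    "GroupTable",
    "LassoResult",
    "OLSResult",
    "mixed_logit_loglik",
    "fit_mixed_logit",
    "mcfadden_r2",
    "build_group_table",
    "cv_lasso",
    "fit_ols",
]

MIXED_FIXED_EFFECTS = ["reward", "guilt", "inequity_abs", "gender", "gender_x_guilt"]

BIG5 = ("neuroticism", "extraversion", "openness", "agreeableness", "conscientiousness")
SES = ("age", "education", "income")


# ---------------------------------------------------------------------------
# Random-intercept mixed logit
# ---------------------------------------------------------------------------

def _gh_nodes(nodes: int) -> tuple[np.ndarray, np.ndarray]:
    b, w = np.polynomial.hermite.hermgauss(nodes)
    return b, w / np.sqrt(np.pi)


def mixed_logit_loglik(
    beta: np.ndarray,
    sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    nodes: int = 8,
) -> float:
    """Marginal log-likelihood of the random-intercept logit.

    Each subject's likelihood integrates the Gaussian intercept deviation
    by ``nodes``-point Gauss-Hermite quadrature:
    ``L_i = sum_k w_k/sqrt(pi) prod_t p_it(sqrt(2) sigma b_k)``.

    ``groups`` must map each row to a 0..G-1 subject index.
    """
    ll, _ = _marginal_ll_and_grad(
        np.append(beta, np.log(max(sigma, 1e-12))), X, y, groups, nodes, want_grad=False
    )
    return ll


def _marginal_ll_and_grad(theta, X, y, groups, nodes, want_grad=True):
    k = X.shape[1]
    beta = theta[:k]
    log_sigma = theta[k]
    sigma = np.exp(log_sigma)
    b, w = _gh_nodes(nodes)
    n_groups = int(groups.max()) + 1

    eta0 = X @ beta                                  # (N,)
    eta = eta0[None, :] + (np.sqrt(2.0) * sigma * b)[:, None]   # (K, N)
    # per-row log Bernoulli likelihood at each node
    ll_rows = y[None, :] * eta - np.logaddexp(0.0, eta)
    # aggregate rows into subjects: (K, G)
    ll_subj = np.zeros((nodes, n_groups))
    for ki in range(nodes):
        ll_subj[ki] = np.bincount(groups, weights=ll_rows[ki], minlength=n_groups)
    log_terms = np.log(w)[:, None] + ll_subj          # (K, G)
    log_Li = logsumexp(log_terms, axis=0)             # (G,)
    total = float(np.sum(log_Li))
    if not want_grad:
        return total, None

    # posterior node weights r_{ik}
    r = np.exp(log_terms - log_Li[None, :])           # (K, G)
    resid = y[None, :] - 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))  # (K, N)
    r_rows = r[:, groups]                             # (K, N)
    grad_beta = (r_rows * resid) @ X                  # (K, k) summed below
    grad_beta = grad_beta.sum(axis=0)
    # d eta / d log_sigma = sqrt(2) sigma b_k
    grad_ls = float(
        np.sum((r_rows * resid) * (np.sqrt(2.0) * sigma * b)[:, None])
    )
    return total, np.append(grad_beta, grad_ls)


@dataclass
class MixedLogitResult:
    """Fixed effects, random-intercept SD and fit statistics."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    pvalues: dict[str, float]
    sigma: float
    loglik: float
    loglik_null: float
    mcfadden_r2: float
    nodes: int
    n_obs: int
    n_subjects: int
    converged: bool
    scale: str = "raw"


def fit_mixed_logit(
    data: pd.DataFrame,
    nodes: int = 8,
    fixed_effects: list[str] | None = None,
) -> MixedLogitResult:
    """Fit the random-intercept logistic regression of cooperate choices.

    ``data`` is long format with columns ``pid``, ``choice``, the regressor
    columns and ``gender``; a ``gender_x_guilt`` column is built if absent.
    Coefficients are reported on the raw regressor scale (any x10^3 display
    scaling belongs to the reporting layer).  McFadden's pseudo-R^2 uses an
    intercept-only ordinary logistic fit as the null model.
    """
    cols = list(fixed_effects) if fixed_effects is not None else list(MIXED_FIXED_EFFECTS)
    df = data.copy()
    if "gender_x_guilt" in cols and "gender_x_guilt" not in df.columns:
        df["gender_x_guilt"] = df["gender"] * df["guilt"]
    if df["pid"].nunique() < 2:
        raise ValueError("mixed logit needs at least 2 participants")
    if nodes < 4:
        raise ValueError("use at least 4 quadrature nodes")
    y = df["choice"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("choice must be binary 0/1")
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols])
    names = ["intercept"] + cols
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design")
    groups = pd.factorize(df["pid"])[0]

    def nll(theta):
        ll, g = _marginal_ll_and_grad(theta, X, y, groups, nodes)
        return -ll, -g

    theta0 = np.zeros(X.shape[1] + 1)
    theta0[-1] = np.log(0.5)
    res = minimize(
        nll,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(np.log(1e-6), np.log(50.0))],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = res.x
    beta = theta[: X.shape[1]]
    sigma = float(np.exp(theta[-1]))
    loglik = -float(res.fun)

    # observed-information SEs from a central-difference Hessian of the
    # negative marginal log-likelihood (analytic gradient differenced)
    p = len(theta)
    H = np.zeros((p, p))
    hstep = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += hstep[j]
        tm[j] -= hstep[j]
        _, gp = _marginal_ll_and_grad(tp, X, y, groups, nodes)
        _, gm = _marginal_ll_and_grad(tm, X, y, groups, nodes)
        H[j] = -(gp - gm) / (2 * hstep[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(p, np.nan)
    se = se_all[: X.shape[1]]
    z = beta / np.where(se > 0, se, np.nan)
    pvals = 2.0 * norm.sf(np.abs(z))

    # intercept-only null logistic: closed form at the sample mean
    pbar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    ll_null = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))

    return MixedLogitResult(
        coefficients=dict(zip(names, beta)),
        standard_errors=dict(zip(names, se)),
        pvalues=dict(zip(names, pvals)),
        sigma=sigma,
        loglik=loglik,
        loglik_null=ll_null,
        mcfadden_r2=mcfadden_r2(loglik, ll_null),
        nodes=nodes,
        n_obs=len(y),
        n_subjects=int(groups.max()) + 1,
        converged=bool(res.success),
    )


def mcfadden_r2(loglik_model: float, loglik_null: float) -> float:
    """McFadden's pseudo-R^2: ``1 - l_model / l_null``."""
    if loglik_model > 0 or loglik_null >= 0:
        raise ValueError("log-likelihoods must be negative (null strictly)")
    return 1.0 - loglik_model / loglik_null


# ---------------------------------------------------------------------------
# Group table
# ---------------------------------------------------------------------------

@dataclass
class GroupTable:
    """Per-participant table feeding the Lasso/OLS group models."""

    frame: pd.DataFrame
    target: str
    predictors: list[str]
    constant_columns: list[str] = field(default_factory=list)


def build_group_table(
    fits: pd.DataFrame,
    participants: pd.DataFrame,
    with_interactions: bool = False,
    center_interactions: bool = False,
) -> GroupTable:
    """Join per-participant beta(Guilt) estimates with covariates.

    The target is the ``abs``-model guilt coefficient.  Specification (1)
    has 9 predictors (gender, five traits, age, education, income);
    specification (2) adds the 8 gender x covariate products (17 total).
    Interactions use the raw covariate unless ``center_interactions`` is
    set.  Constant (zero-variance) columns — e.g. every gender interaction
    in a single-gender cohort — are listed in ``constant_columns`` for the
    caller to drop.
    """
    abs_fits = fits[fits["model"] == "abs"] if "model" in fits.columns else fits
    if "beta_guilt" not in abs_fits.columns:
        raise ValueError("fits table lacks a beta_guilt column")
    covars = list(BIG5) + list(SES)
    missing = [c for c in ("pid", "gender", *covars) if c not in participants.columns]
    if missing:
        raise ValueError(f"participants table missing columns: {missing}")
    merged = abs_fits[["pid", "beta_guilt"]].merge(
        participants[["pid", "gender", *covars]], on="pid", how="left", validate="1:1"
    )
    if merged["gender"].isna().any():
        orphans = merged.loc[merged["gender"].isna(), "pid"].tolist()
        raise ValueError(f"no participant row for pid(s): {orphans}")

    predictors = ["gender"] + covars
    if with_interactions:
        for c in covars:
            x = merged[c].astype(float)
            if center_interactions:
                x = x - x.mean()
            merged[f"gender_x_{c}"] = merged["gender"] * x
        predictors = predictors + [f"gender_x_{c}" for c in covars]

    constant = [c for c in predictors if merged[c].nunique() <= 1]
    return GroupTable(
        frame=merged,
        target="beta_guilt",
        predictors=predictors,
        constant_columns=constant,
    )


# ---------------------------------------------------------------------------
# Lasso with ten-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LassoResult:
    """Cross-validated Lasso fit with path and chosen-penalty bookkeeping.

    ``lambdas`` descend; the objective is ``(1/2n)||y - Xb||^2 + lambda
    ||b||_1`` with predictors standardized to unit (population) variance.
    ``coefficients`` are back-transformed to the original covariate scale;
    ``coefficients_std`` stay on the standardized scale the penalty saw.
    """

    lambdas: np.ndarray
    coef_path: np.ndarray          # (n_lambdas, n_predictors), standardized scale
    cv_mean: np.ndarray
    cv_se: np.ndarray
    chosen_lambda: float
    rule: str
    coefficients: dict[str, float]     # original scale, incl. intercept
    coefficients_std: dict[str, float]
    dropped: list[str] = field(default_factory=list)
    scale: str = "raw"


def cv_lasso(
    table: GroupTable,
    folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    n_lambdas: int = 100,
    lambdas: np.ndarray | None = None,
) -> LassoResult:
    """L1-penalized regression of beta(Guilt) with a CV-chosen penalty.

    The lambda grid is log-spaced from the smallest value that zeroes every
    coefficient down to ``1e-3`` of it.  Fold assignment is a seeded
    shuffle; ``lambda_rule`` is ``"min"`` (CV-error minimum) or ``"1se"``
    (largest lambda within one standard error of the minimum).  The
    intercept is unpenalized.  Zero-variance predictors are dropped (and
    reported) before standardization.
    """
    from sklearn.linear_model import Lasso
    from sklearn.model_selection import KFold

    df = table.frame
    y = df[table.target].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("target has zero variance")
    n = len(y)
    if n <= folds:
        raise ValueError(f"need more than {folds} rows for {folds}-fold CV, got {n}")
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")

    keep = [p for p in table.predictors if df[p].nunique() > 1]
    dropped = [p for p in table.predictors if p not in keep]
    X = df[keep].to_numpy(dtype=float)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)  # population sd: unit-variance columns, (1/2n) objective
    Xs = (X - x_mean) / x_sd
    y_mean = y.mean()
    yc = y - y_mean

    if lambdas is None:
        lam_max = float(np.max(np.abs(Xs.T @ yc)) / n)
        lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)
    else:
        lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    n_lambdas = len(lambdas)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_err = np.zeros((n_lambdas, folds))
    for fi, (tr, te) in enumerate(kf.split(Xs)):
        for li, lam in enumerate(lambdas):
            model = Lasso(alpha=lam, fit_intercept=True, tol=1e-10, max_iter=100_000)
            model.fit(Xs[tr], yc[tr])
            pred = model.predict(Xs[te])
            cv_err[li, fi] = float(np.mean((yc[te] - pred) ** 2))
    cv_mean = cv_err.mean(axis=1)
    cv_se = cv_err.std(axis=1, ddof=1) / np.sqrt(folds)

    i_min = int(np.argmin(cv_mean))
    if lambda_rule == "min":
        chosen = float(lambdas[i_min])
    else:
        thresh = cv_mean[i_min] + cv_se[i_min]
        ok = np.where(cv_mean <= thresh)[0]
        chosen = float(lambdas[ok.min()])  # grid descends: min index = largest lambda

    coef_path = np.zeros((n_lambdas, len(keep)))
    for li, lam in enumerate(lambdas):
        m = Lasso(alpha=lam, fit_intercept=True, tol=1e-10, max_iter=100_000)
        m.fit(Xs, yc)
        coef_path[li] = m.coef_

    final = Lasso(alpha=chosen, fit_intercept=True, tol=1e-12, max_iter=500_000)
    final.fit(Xs, yc)
    coef_std = final.coef_
    coef_orig = coef_std / x_sd
    intercept = y_mean + float(final.intercept_) - float(coef_orig @ x_mean)

    coefficients = {"intercept": intercept}
    coefficients.update(dict(zip(keep, coef_orig)))
    for p in dropped:
        coefficients[p] = 0.0
    return LassoResult(
        lambdas=lambdas,
        coef_path=coef_path,
        cv_mean=cv_mean,
        cv_se=cv_se,
        chosen_lambda=chosen,
        rule=lambda_rule,
        coefficients=coefficients,
        coefficients_std=dict(zip(keep, coef_std)),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# OLS cross-check
# ---------------------------------------------------------------------------

@dataclass
class OLSResult:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    n: int
    scale: str = "raw"


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns implicated in a rank deficiency.

    Exact duplicates are both named; otherwise QR pivoting flags the
    dependent columns.
    """
    from scipy.linalg import qr

    flagged: set[str] = set()
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            if np.allclose(X[:, i], X[:, j]):
                flagged.update((names[i], names[j]))
    if not flagged:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        rank = np.linalg.matrix_rank(X)
        flagged.update(names[p] for p in piv[rank:])
    return sorted(flagged)


def fit_ols(table: GroupTable) -> OLSResult:
    """Ordinary least squares on the group table with two-sided t-tests.

    Raises on rank deficiency, naming the collinear columns — the failure
    mode the penalized fit exists to avoid.
    """
    import statsmodels.api as sm

    df = table.frame
    names = list(table.predictors)
    X = df[names].to_numpy(dtype=float)
    y = df[table.target].to_numpy(dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"need n > {X.shape[1] + 1} rows, got {len(y)}")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    all_names = ["intercept"] + names
    return OLSResult(
        coefficients=dict(zip(all_names, fit.params)),
        standard_errors=dict(zip(all_names, fit.bse)),
        pvalues=dict(zip(all_names, fit.pvalues)),
        r_squared=float(fit.rsquared),
        n=len(y),
    )
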