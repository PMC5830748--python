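"""Hypothesis-testing stages.

* variance heterogeneity between treatment groups (Levene's test) — the
  signature of stress-inflated inter-individual variability;
* linear mixed models for treatment effects on the distance-to-centroid
  statistic (ED) and physiological endpoints, with a random intercept per
  mesocosm nested under treatment (Gaussian fits by REML; Poisson counts
  by maximum likelihood with Gauss-Hermite quadrature);
* linear models linking isotope anomalies to physiology, with AIC-based
  selection of the most parsimonious predictor set;
* a logistic discriminator of stressed vs reference populations, reported
  with odds ratios, ROC curve, AUC and sensitivity/specificity at a
  Youden-J cutoff.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """A model fit failed to converge; the message carries diagnostics."""


class SeparationWarning(UserWarning):
    """Logistic classes are (quasi-)separated; coefficients are unstable."""


@dataclass
class VarianceTestResult:
    variable: str
    groups: list[str]
    statistic: float
    df_num: int
    df_den: int
    p_value: float
    center: str
    degenerate: bool = False


@dataclass
class ModelFit:
    """A fitted (generalised/mixed) linear model.

    ``params`` has one row per coefficient with columns
    estimate / se / stat / p; ``stat`` is a t statistic for Gaussian
    fits and a z statistic otherwise.  ``aic = 2k - 2*loglik`` with k the
    number of estimated parameters (for REML fits the restricted
    log-likelihood is used and comparisons are only valid across models
    with identical fixed effects).
    """

    formula: str
    family: str
    link: str
    params: pd.DataFrame
    loglik: float
    k: int
    n: int
    dropped_n: int = 0
    random_variance: float | None = None
    resid_variance: float | None = None
    boundary: bool = False
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    cutoff: float
    sensitivity: float
    specificity: float


@dataclass
class ClassifierReport:
    """Logistic stress discriminator: coefficients, odds ratios, ROC."""

    response: str
    predictors: list[str]
    params: pd.DataFrame  # estimate / se / stat / p / odds_ratio
    loglik: float
    k: int
    n: int
    separation: bool = False
    auc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    cutoff: float | None = None
    roc: RocResult | None = None
    fitted: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def odds_ratios(self) -> pd.Series:
        return self.params["odds_ratio"]


# ---------------------------------------------------------------------------
# variance heterogeneity


def levene_test(
    groups: Mapping[str, Sequence[float]], center: str = "mean", variable: str = ""
) -> VarianceTestResult:
    """Levene's test for homogeneity of variance across groups.

    One-way ANOVA on absolute deviations from each group's centre
    (``center='mean'`` is Levene's original form, ``'median'`` the
    Brown-Forsythe variant).
    """
    labels = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(values) < 2:
        raise ValueError("levene_test requires at least 2 groups")
    for g, v in zip(labels, values):
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    k = len(values)
    n_total = sum(len(v) for v in values)
    centre = np.mean if center == "mean" else np.median
    degenerate = all(np.allclose(v, centre(v)) for v in values)
    if degenerate:
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.levene(*values, center=center)
    return VarianceTestResult(
        variable=variable,
        groups=labels,
        statistic=float(stat),
        df_num=k - 1,
        df_den=n_total - k,
        p_value=float(p),
        center=center,
        degenerate=degenerate,
    )


def survival_test(groups: Mapping[str, Sequence[float]]) -> dict:
    """Thin nonparametric comparison of mesocosm survival between groups.

    Mann-Whitney U for two groups, Kruskal-Wallis otherwise.
    """
    values = [np.asarray(v, float) for v in groups.values()]
    if len(values) == 2:
        stat, p = sps.mannwhitneyu(*values, alternative="two-sided")
        method = "mann-whitney"
    else:
        stat, p = sps.kruskal(*values)
        method = "kruskal-wallis"
    return {"method": method, "statistic": float(stat), "p_value": float(p)}


# ---------------------------------------------------------------------------
# mixed models


def _complete_cases(df: pd.DataFrame, cols: Sequence[str]) -> tuple[pd.DataFrame, int]:
    present = [c for c in cols if c in df.columns]
    sub = df.dropna(subset=present)
    dropped = len(df) - len(sub)
    if dropped:
        logger.info("dropped %d incomplete records (columns %s)", dropped, present)
    return sub, dropped


def _formula_columns(terms: Sequence[str]) -> list[str]:
    """Bare column names referenced by simple formula terms like C(x)."""
    cols = []
    for t in terms:
        t = t.strip()
        if t.startswith("C(") and t.endswith(")"):
            t = t[2:-1]
        cols.append(t.split(",")[0].strip())
    return cols


def fit_mixed_model(
    df: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    group: str,
    family: str = "gaussian",
    reml: bool = True,
) -> ModelFit:
    """Random-intercept model for a clustered (mesocosm) design.

    Gaussian responses are fitted by REML (statsmodels ``MixedLM``) with t
    statistics on fixed effects; Poisson counts by maximum likelihood with
    a log link, the random intercept integrated out by 25-node
    Gauss-Hermite quadrature, and z statistics.  The random intercept is
    always retained; a near-zero estimated intercept variance sets the
    ``boundary`` flag rather than removing the term.
    """
    if family not in ("gaussian", "poisson"):
        raise ValueError(f"unsupported family {family!r}")
    cols = [response, group, *_formula_columns(fixed)]
    data, dropped = _complete_cases(df, cols)
    if data[group].nunique() < 2:
        raise ValueError(f"random grouping '{group}' needs >= 2 levels")
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{response} ~ {rhs}"
    if family == "poisson":
        y = data[response].to_numpy(float)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson family requires nonnegative counts")
        return _fit_poisson_glmm(data, response, fixed, group, formula, dropped)

    model = smf.mixedlm(formula, data=data, groups=data[group])
    res = _fit_mixedlm(model, reml, formula)
    fe = res.fe_params
    params = pd.DataFrame(
        {
            "estimate": fe,
            "se": res.bse_fe,
            "stat": res.tvalues[fe.index],
            "p": res.pvalues[fe.index],
        }
    )
    re_var = float(res.cov_re.iloc[0, 0])
    resid_var = float(res.scale)
    k = len(fe) + 2  # random-intercept variance + residual variance
    return ModelFit(
        formula=formula,
        family="gaussian",
        link="identity",
        params=params,
        loglik=float(res.llf),
        k=k,
        n=len(data),
        dropped_n=dropped,
        random_variance=re_var,
        resid_variance=resid_var,
        boundary=re_var < 1e-8 * max(resid_var, 1e-12),
    )


def _fit_mixedlm(model, reml: bool, formula: str):
    """Fit a MixedLM, walking an optimizer ladder on non-convergence.

    Variance estimates on the zero boundary are legitimate, but some
    optimizers stall there with spurious fixed effects, so boundary fits
    are verified against the exact OLS solution (zero random variance
    makes GLS collapse to OLS).
    """

    def _boundary_ok(res) -> bool:
        re_var = float(res.cov_re.iloc[0, 0])
        if re_var > 1e-6 * max(float(res.scale), 1e-12):
            return True  # interior estimate: nothing to cross-check
        beta_ols = np.linalg.lstsq(model.exog, model.endog, rcond=None)[0]
        scale = max(np.abs(beta_ols).max(), 1e-8)
        return bool(np.max(np.abs(res.fe_params.to_numpy() - beta_ols)) < 1e-4 * scale)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tried = [None, "powell", "nm", "cg"]
        for method in tried:
            try:
                res = (
                    model.fit(reml=reml)
                    if method is None
                    else model.fit(reml=reml, method=method)
                )
            except (np.linalg.LinAlgError, ValueError):
                continue
            if (
                res.converged
                and np.all(np.isfinite(res.fe_params))
                and _boundary_ok(res)
            ):
                return res
    raise ConvergenceError(
        f"MixedLM did not converge for '{formula}' "
        f"(n={model.nobs:.0f}; optimizers tried: default, powell, nm, cg)"
    )


def _design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix with intercept for a list of simple terms."""
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0
    for t in terms:
        col = _formula_columns([t])[0]
        v = data[col]
        if t.strip().startswith("C(") or v.dtype == object or v.dtype == bool:
            dummies = pd.get_dummies(v.astype(str), prefix=col, drop_first=True)
            for c in dummies.columns:
                X[c] = dummies[c].astype(float)
        else:
            X[col] = v.astype(float)
    return X


def _fit_poisson_glmm(
    data: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    group: str,
    formula: str,
    dropped: int,
    n_quad: int = 25,
) -> ModelFit:
    """ML Poisson random-intercept model via Gauss-Hermite quadrature."""
    y = data[response].to_numpy(float)
    X = _design_matrix(data, fixed)
    names = list(X.columns)
    Xv = X.to_numpy(float)
    codes, _ = pd.factorize(data[group])
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    const = -gammaln(y + 1.0).sum()
    n_groups = codes.max() + 1

    def negloglik(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = Xv @ beta
        # per-group, per-node joint Poisson log density
        shift = np.sqrt(2.0) * sigma * nodes  # (q,)
        contrib = np.zeros((n_groups, n_quad))
        lam_log = eta[:, None] + shift[None, :]  # (n, q)
        terms = y[:, None] * lam_log - np.exp(lam_log)
        np.add.at(contrib, codes, terms)
        ll = logsumexp(contrib + log_w[None, :], axis=1).sum() + const
        return -ll

    start_glm = sm.GLM(y, Xv, family=sm.families.Poisson()).fit()
    theta0 = np.r_[start_glm.params, np.log(0.3)]
    res = minimize(negloglik, theta0, method="L-BFGS-B")
    if not res.success:
        raise ConvergenceError(
            f"Poisson GLMM did not converge for '{formula}': {res.message}"
        )
    beta = res.x[:-1]
    sigma2 = float(np.exp(2 * res.x[-1]))
    # observed-information SEs for the fixed effects
    from statsmodels.tools.numdiff import approx_hess1

    hess = approx_hess1(res.x, negloglik)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
    z = beta / se
    params = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "stat": z,
            "p": 2 * sps.norm.sf(np.abs(z)),
        },
        index=names,
    )
    return ModelFit(
        formula=formula,
        family="poisson",
        link="log",
        params=params,
        loglik=float(-res.fun),
        k=len(beta) + 1,
        n=len(y),
        dropped_n=dropped,
        random_variance=sigma2,
        boundary=sigma2 < 1e-6,
    )


# ---------------------------------------------------------------------------
# linear models and AIC selection


def _check_rank(X: pd.DataFrame) -> None:
    Xv = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name columns whose removal restores full rank
        bad = [
            c
            for c in X.columns
            if c != "Intercept"
            and np.linalg.matrix_rank(X.drop(columns=c).to_numpy(float)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_linear_model(
    df: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    link: str = "identity",
) -> ModelFit:
    """Linear model of an isotope anomaly (or change) on physiology.

    ``link='identity'`` is ordinary least squares with t statistics;
    ``link='log'`` is a Gaussian GLM with log link (for strictly positive
    responses such as absolute isotope changes), reported with z
    statistics.
    """
    cols = [response, *_formula_columns(predictors)]
    data, dropped = _complete_cases(df, cols)
    y = data[response].to_numpy(float)
    X = _design_matrix(data, predictors)
    _check_rank(X)
    if link == "identity":
        res = sm.OLS(y, X).fit()
        stat, p = res.tvalues, res.pvalues
        loglik, k = float(res.llf), len(res.params) + 1  # + residual variance
        resid_var = float(res.mse_resid)
    elif link == "log":
        fam = sm.families.Gaussian(link=sm.families.links.Log())
        res = sm.GLM(y, X, family=fam).fit()
        stat, p = res.tvalues, res.pvalues
        loglik, k = float(res.llf), len(res.params) + 1
        resid_var = float(res.scale)
    else:
        raise ValueError(f"unsupported link {link!r}")
    params = pd.DataFrame(
        {"estimate": res.params, "se": res.bse, "stat": stat, "p": p}
    )
    return ModelFit(
        formula=f"{response} ~ {' + '.join(predictors) if predictors else '1'}",
        family="gaussian",
        link=link,
        params=params,
        loglik=loglik,
        k=k,
        n=len(y),
        dropped_n=dropped,
        resid_variance=resid_var,
    )


def select_by_aic(
    df: pd.DataFrame,
    response: str,
    candidate_sets: Sequence[Sequence[str]],
    fit: Callable[..., ModelFit] | None = None,
    **fit_kwargs,
) -> tuple[ModelFit, pd.DataFrame]:
    """Fit candidate predictor sets and return the minimum-AIC model.

    All candidates are fitted on the identical complete-case subset over
    the union of predictors, so AIC values are comparable.  Ties break
    toward fewer parameters; failing candidates are excluded with a logged
    reason.
    """
    if not candidate_sets:
        raise ValueError("no candidate predictor sets supplied")
    fit = fit or fit_linear_model
    union = sorted({c for s in candidate_sets for c in _formula_columns(s)})
    data, _ = _complete_cases(df, [response, *union])
    fits: list[tuple[float, int, int, ModelFit, Sequence[str]]] = []
    rows = []
    for i, cand in enumerate(candidate_sets):
        try:
            m = fit(data, response, list(cand), **fit_kwargs)
        except Exception as err:  # noqa: BLE001 - candidate exclusion is logged
            logger.info("candidate %s excluded: %s", list(cand), err)
            rows.append({"predictors": " + ".join(cand) or "1", "aic": np.nan,
                         "k": np.nan, "error": str(err)})
            continue
        fits.append((m.aic, m.k, i, m, cand))
        rows.append({"predictors": " + ".join(cand) or "1", "aic": m.aic,
                     "k": m.k, "error": ""})
    if not fits:
        raise RuntimeError("every candidate model failed to fit")
    fits.sort(key=lambda t: (round(t[0], 10), t[1], t[2]))
    ranking = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    return fits[0][3], ranking


def all_subsets(predictors: Sequence[str], include_empty: bool = False):
    """Every subset of a predictor list, smallest first (for AIC search)."""
    start = 0 if include_empty else 1
    for r in range(start, len(predictors) + 1):
        yield from (list(c) for c in itertools.combinations(predictors, r))


# ---------------------------------------------------------------------------
# logistic discriminator and ROC


def fit_logistic(
    df: pd.DataFrame, response: str, predictors: Sequence[str]
) -> ClassifierReport:
    """Maximum-likelihood logistic regression of stressed(1)/reference(0).

    Odds ratios are exp(coefficient).  Complete or quasi-complete
    separation raises :class:`SeparationWarning` and flags the report;
    coefficients are then unstable and should not be interpreted.
    """
    cols = [response, *_formula_columns(predictors)]
    data, dropped = _complete_cases(df, cols)
    y = data[response].to_numpy(float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("response must contain both classes coded 0/1")
    X = _design_matrix(data, predictors)
    _check_rank(X)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200)
    fitted = np.asarray(res.predict(X))
    if not separation:
        # quasi-separation: fitted probabilities saturate at the boundary
        eps = 1e-6
        saturated = (fitted > 1 - eps) | (fitted < eps)
        separation = bool(saturated.any()) or bool(
            np.any(np.abs(res.params) > 50)
        )
    if separation:
        warnings.warn(
            f"(quasi-)separation detected in logistic fit of '{response}'; "
            "coefficients are unstable",
            SeparationWarning,
            stacklevel=2,
        )
    params = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "stat": res.tvalues,
            "p": res.pvalues,
            "odds_ratio": np.exp(res.params),
        }
    )
    return ClassifierReport(
        response=response,
        predictors=list(predictors),
        params=params,
        loglik=float(res.llf),
        k=len(res.params),
        n=len(y),
        separation=separation,
        fitted=fitted,
        labels=y,
    )


def roc_analysis(scores, labels, cutoff: str = "youden") -> RocResult:
    """ROC curve, trapezoidal AUC and the operating point at the cutoff.

    The AUC equals the normalised Mann-Whitney U statistic of the scores
    between classes; the default cutoff maximises Youden's J
    (sensitivity + specificity - 1).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    if cutoff != "youden":
        raise ValueError(f"unknown cutoff rule {cutoff!r}")
    j = tpr - fpr
    i = int(np.argmax(j))
    return RocResult(
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        cutoff=float(thresholds[i]),
        sensitivity=float(tpr[i]),
        specificity=float(1.0 - fpr[i]),
    )


def classify_stress(
    df: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    standardize: bool = False,
    cutoff: str = "youden",
) -> ClassifierReport:
    """Fit the logistic stress discriminator and evaluate it by ROC/AUC."""
    data = df.copy()
    if standardize:
        for col in _formula_columns(predictors):
            v = data[col].astype(float)
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"predictor '{col}' has zero spread")
            data[col] = (v - v.mean()) / sd
    report = fit_logistic(data, response, predictors)
    roc = roc_analysis(report.fitted, report.labels, cutoff=cutoff)
    report.auc = roc.auc
    report.sensitivity = roc.sensitivity
    report.specificity = roc.specificity
    report.cutoff = roc.cutoff
    report.roc = roc
    return report
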