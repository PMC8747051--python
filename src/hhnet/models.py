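"""Association models: survey-weighted logistic regression per round, a
pooled random-intercept (survey-round) logistic model, and SD-scaled
average marginal effects.

Each exposure (one structural or compositional variable) is fitted in its
own model, crude and adjusted, because the exposures are mutually
correlated.  Per-round models use weight-scaled maximum likelihood with
cluster-robust (sandwich) standard errors on the primary sampling unit.
The pooled model adds a Gaussian random intercept on the survey round,
integrated out by adaptive Gauss-Hermite quadrature; sampling weights
enter it as normalized pseudo-likelihood scaling.

Average marginal effects are reported in percentage points: the mean
change in predicted probability for a one-weighted-SD increase above each
observation's value (continuous exposures) or for a discrete change from
the reference level (categorical exposures), with delta-method intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.optimize
import scipy.special
import statsmodels.api as sm
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_hess2

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "MarginalEffect",
    "fit_weighted_logistic",
    "fit_random_intercept_logistic",
    "average_marginal_effect",
    "run_association_suite",
    "significance_stars",
    "DEFAULT_COVARIATES",
    "DEFAULT_EXPOSURES",
    "REFERENCE_LEVELS",
]

#: Covariates of the adjusted models (respondent and household characteristics).
DEFAULT_COVARIATES: tuple[str, ...] = (
    "resp_age_years",
    "resp_education",
    "residence",
    "coresident_husband",
    "head_sex",
    "wealth_tercile",
    "earnings",
)

#: Exposures analysed one per model: structural then compositional.
DEFAULT_EXPOSURES: tuple[str, ...] = (
    "degree",
    "es_class",
    "constraint",
    "age_sd",
    "iqv_sex",
    "iqv_education",
    "iqv_de_facto_diverse",
    "iqv_de_jure_diverse",
    "iqv_kinship",
)

#: Reference levels for categorical terms (Treatment coding).
REFERENCE_LEVELS: dict[str, str] = {
    "es_class": "low",
    "resp_education": "none",
    "education": "none",
    "residence": "rural",
    "earnings": "not_working",
    "wealth_tercile": "poor",
    "head_sex": "male",
}

#: |coefficient| beyond which a logistic fit is flagged as separated.
_SEPARATION_BOUND = 12.0


class SeparationWarning(UserWarning):
    pass


@dataclass
class ModelFit:
    """A fitted logistic model (weighted GLM or random-intercept)."""

    kind: str  # "weighted_glm" | "random_intercept"
    formula: str
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    n: int
    n_dropped: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    sigma_u: float | None = None
    sigma_u_se: float | None = None
    loglike: float | None = None
    design_info: object | None = None
    frame: pd.DataFrame | None = None
    weights: np.ndarray | None = None

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Odds ratios with Wald confidence intervals and p-values."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        wald = self.params / self.bse
        p = 2 * norm.sf(np.abs(wald))
        with np.errstate(over="ignore"):  # separated fits overflow to inf
            return pd.DataFrame(
                {
                    "odds_ratio": np.exp(self.params),
                    "ci_low": np.exp(self.params - z * self.bse),
                    "ci_high": np.exp(self.params + z * self.bse),
                    "p_value": p,
                },
                index=self.params.index,
            )


@dataclass(frozen=True)
class MarginalEffect:
    """Average marginal effect in percentage points."""

    variable: str
    level: str | None  # non-reference level for categorical variables
    effect_pp: float
    se_pp: float
    ci_low: float
    ci_high: float
    p_value: float
    scaling: str  # per_sd_above_mean | discrete_from_reference


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _is_categorical(series: pd.Series) -> bool:
    return (
        series.dtype == object
        or isinstance(series.dtype, pd.CategoricalDtype)
        or series.dtype == bool
    )


def _term_for(col: str, data: pd.DataFrame) -> str:
    if _is_categorical(data[col]):
        ref = REFERENCE_LEVELS.get(col)
        if ref is None:
            levels = sorted(data[col].dropna().astype(str).unique())
            ref = levels[0]
        return f"C({col}, Treatment(reference={ref!r}))"
    return col


def build_formula(outcome: str, exposure: str, covariates: Sequence[str], data: pd.DataFrame) -> str:
    terms = [_term_for(exposure, data)] + [_term_for(c, data) for c in covariates]
    return f"{outcome} ~ " + " + ".join(terms)


def _model_frame(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str],
    extra: Sequence[str],
) -> tuple[pd.DataFrame, int]:
    cols = [outcome, exposure, *covariates, *extra]
    cols = list(dict.fromkeys(c for c in cols if c is not None))
    frame = table[cols].copy()
    # booleans participate as 0/1 numeric except the exposure, which keeps
    # its categorical identity for reference coding
    for c in frame.columns:
        if frame[c].dtype == bool and c != exposure:
            frame[c] = frame[c].astype(int)
    if frame[exposure].dtype == bool:
        frame[exposure] = frame[exposure].map({False: "absent", True: "present"})
    n0 = len(frame)
    frame = frame.dropna()
    frame[outcome] = frame[outcome].astype(int)
    return frame.reset_index(drop=True), n0 - len(frame)


def fit_weighted_logistic(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    weight_col: str = "weight",
    cluster_col: str | None = "cluster_id",
) -> ModelFit:
    """Survey-weighted logistic regression with cluster-robust errors.

    Weights are normalized to sum to the analysed sample size and scale the
    log-likelihood (IRLS via a binomial GLM), so a record of weight 2 is
    equivalent to the same record duplicated.  Standard errors are sandwich
    estimates clustered on ``cluster_col`` (the primary sampling unit); pass
    ``None`` for plain heteroscedasticity-robust errors.
    """
    extra = [weight_col] + ([cluster_col] if cluster_col else [])
    frame, n_dropped = _model_frame(table, outcome, exposure, covariates, extra)
    if len(frame) == 0:
        raise ValueError("empty model frame after listwise deletion")
    formula = build_formula(outcome, exposure, covariates, frame)
    y, X = patsy.dmatrices(formula, frame, return_type="dataframe")
    w = frame[weight_col].to_numpy(dtype=float)
    w = w * len(w) / w.sum()

    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    import warnings

    flags: list[str] = []
    with warnings.catch_warnings():
        # statsmodels warns that sandwich covariances with var_weights are
        # "not fully supported"; for the binomial log-likelihood the weighted
        # score contributions are exactly what the survey sandwich needs
        warnings.filterwarnings("ignore", message="cov_type not fully supported")
        if cluster_col and frame[cluster_col].nunique() >= 2:
            res = model.fit(cov_type="cluster", cov_kwds={"groups": frame[cluster_col]})
        else:
            if cluster_col:
                flags.append("single_cluster_hc1")
            res = model.fit(cov_type="HC1")

    if not res.converged:
        flags.append("non_convergence")
    if np.abs(res.params.to_numpy()).max() > _SEPARATION_BOUND:
        flags.append("separation")
        logger.warning("possible separation in %s (max |coef| > %s)", formula, _SEPARATION_BOUND)
    return ModelFit(
        kind="weighted_glm",
        formula=formula,
        params=res.params,
        bse=res.bse,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        n=len(frame),
        n_dropped=n_dropped,
        converged=res.converged,
        flags=flags,
        loglike=float(res.llf),
        design_info=X.design_info,
        frame=frame,
        weights=w,
    )


class RandomInterceptLogit:
    """Logistic regression with a Gaussian random intercept per group,
    integrated by adaptive Gauss-Hermite quadrature.

    The marginal log-likelihood for group g is

        log ∫ Π_i p_i(β, u)^{y_i} (1 - p_i)^{1 - y_i} φ(u; 0, σ²) du ,

    approximated on quadrature nodes recentred at the mode of the
    integrand and rescaled by its curvature (so a handful of nodes is
    accurate even for large groups).  Observation log-likelihood terms can
    be scaled by normalized weights (pseudo-likelihood).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        groups: np.ndarray,
        weights: np.ndarray | None = None,
        n_points: int = 15,
    ) -> None:
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.asarray(X, dtype=float)
        if weights is None:
            weights = np.ones_like(self.y)
        w = np.asarray(weights, dtype=float)
        self.w = w * len(w) / w.sum()
        codes, self.group_labels = pd.factorize(np.asarray(groups))
        self.group_idx = [np.flatnonzero(codes == g) for g in range(len(self.group_labels))]
        if len(self.group_idx) < 2:
            raise ValueError("random-intercept model needs at least 2 groups; fit per round instead")
        self.nodes, self.quad_weights = np.polynomial.hermite.hermgauss(n_points)

    def _group_loglike(self, beta: np.ndarray, sigma: float, idx: np.ndarray) -> float:
        y, w = self.y[idx], self.w[idx]
        eta0 = self.X[idx] @ beta

        def h(u: float | np.ndarray):
            eta = eta0[:, None] + np.atleast_1d(u)[None, :]
            ll = y[:, None] * eta - np.logaddexp(0.0, eta)
            return (w[:, None] * ll).sum(axis=0)

        # Newton search for the mode of h(u) - u^2 / (2 sigma^2)
        u_hat = 0.0
        for _ in range(50):
            p = expit(eta0 + u_hat)
            grad = float((w * (y - p)).sum()) - u_hat / sigma**2
            hess = -float((w * p * (1 - p)).sum()) - 1.0 / sigma**2
            step = -grad / hess
            u_hat += step
            if abs(step) < 1e-10:
                break
        p = expit(eta0 + u_hat)
        curv = float((w * p * (1 - p)).sum()) + 1.0 / sigma**2
        s = 1.0 / np.sqrt(curv)

        u_nodes = u_hat + np.sqrt(2.0) * s * self.nodes
        g_vals = h(u_nodes) - u_nodes**2 / (2 * sigma**2) - np.log(sigma * np.sqrt(2 * np.pi))
        return float(
            np.log(np.sqrt(2.0) * s) + logsumexp(np.log(self.quad_weights) + self.nodes**2 + g_vals)
        )

    def loglike(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = float(np.exp(log_sigma))
        return sum(self._group_loglike(beta, sigma, idx) for idx in self.group_idx)

    def fit(self, start_beta: np.ndarray | None = None, start_sigma: float = 0.3):
        k = self.X.shape[1]
        if start_beta is None:
            glm = sm.GLM(self.y, self.X, family=sm.families.Binomial(), var_weights=self.w)
            start_beta = glm.fit().params
        x0 = np.r_[start_beta, np.log(start_sigma)]
        bounds = [(None, None)] * k + [(np.log(1e-6), np.log(10.0))]
        res = scipy.optimize.minimize(
            lambda p: -self.loglike(p),
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        return res


def fit_random_intercept_logistic(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    group_col: str = "round",
    weight_col: str | None = "weight",
    n_points: int = 15,
) -> ModelFit:
    """Pooled logistic model with a random intercept on the survey round.

    The random-effect variance is boundary-prone when only a few rounds
    are pooled; a near-zero estimate is flagged (``variance_boundary``)
    rather than treated as an error, and the fixed effects then coincide
    with the plain pooled logistic fit.
    """
    extra = [group_col] + ([weight_col] if weight_col else [])
    frame, n_dropped = _model_frame(table, outcome, exposure, covariates, extra)
    if frame[group_col].nunique() < 2:
        raise ValueError("only one group present; use the per-round weighted fit instead")
    formula = build_formula(outcome, exposure, covariates, frame)
    y, X = patsy.dmatrices(formula, frame, return_type="dataframe")
    w = frame[weight_col].to_numpy(dtype=float) if weight_col else None

    model = RandomInterceptLogit(
        y.to_numpy().ravel(), X.to_numpy(), frame[group_col].to_numpy(), weights=w, n_points=n_points
    )
    res = model.fit()
    k = X.shape[1]
    params = res.x
    sigma = float(np.exp(params[-1]))
    flags = []
    if not res.success:
        flags.append("non_convergence")
    if sigma < 1e-3:
        flags.append("variance_boundary")

    # observed-information covariance; falls back to fixed-sigma curvature
    # when the boundary makes the full Hessian singular
    cov_full = None
    try:
        H = approx_hess2(params, lambda p: -model.loglike(p))
        cov_full = np.linalg.inv(H)
        if not np.all(np.diag(cov_full)[:k] > 0):
            cov_full = None
    except np.linalg.LinAlgError:
        cov_full = None
    if cov_full is None:
        H = approx_hess2(params[:k], lambda b: -model.loglike(np.r_[b, params[-1]]))
        cov_beta = np.linalg.inv(H)
        sigma_se = None
        flags.append("hessian_fallback")
    else:
        cov_beta = cov_full[:k, :k]
        sigma_se = float(np.sqrt(max(cov_full[-1, -1], 0.0)) * sigma)  # delta from log sigma

    names = list(X.columns)
    if np.abs(params[:k]).max() > _SEPARATION_BOUND:
        flags.append("separation")
    return ModelFit(
        kind="random_intercept",
        formula=formula,
        params=pd.Series(params[:k], index=names),
        bse=pd.Series(np.sqrt(np.maximum(np.diag(cov_beta), 0.0)), index=names),
        cov=pd.DataFrame(cov_beta, index=names, columns=names),
        n=len(frame),
        n_dropped=n_dropped,
        converged=bool(res.success),
        flags=flags,
        sigma_u=sigma,
        sigma_u_se=sigma_se,
        loglike=float(-res.fun),
        design_info=X.design_info,
        frame=frame,
        weights=model.w,
    )


def _weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    mean = np.average(x, weights=w)
    return float(np.sqrt(np.average((x - mean) ** 2, weights=w)))


def _predict(fit: ModelFit, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predicted probability and its design matrix under the fitted fixed
    effects (random intercept at its mean of zero for pooled models)."""
    (X,) = patsy.build_design_matrices([fit.design_info], data, return_type="dataframe")
    eta = X.to_numpy() @ fit.params.to_numpy()
    return expit(eta), X.to_numpy()


def average_marginal_effect(
    fit: ModelFit,
    variable: str,
    alpha: float = 0.05,
) -> list[MarginalEffect]:
    """SD-scaled (continuous) or reference-contrast (categorical) AME.

    Continuous: mean over observations of
    ``P(y=1 | x_i, variable + 1 weighted SD) - P(y=1 | x_i)``, x 100.
    Categorical: for each non-reference level, mean of
    ``P(y=1 | level) - P(y=1 | reference)``, x 100.  Intervals are
    delta-method normal intervals propagating the coefficient covariance.
    """
    from scipy.stats import norm

    if fit.frame is None or fit.design_info is None:
        raise ValueError("fit does not carry its model frame; refit with this package")
    if variable not in fit.frame.columns:
        raise KeyError(f"variable {variable!r} is not in the fitted model frame")
    data = fit.frame
    w = fit.weights if fit.weights is not None else np.ones(len(data))
    V = fit.cov.to_numpy()
    z = norm.ppf(1 - alpha / 2)
    results = []

    def _one(data_hi: pd.DataFrame, data_lo: pd.DataFrame, level: str | None, scaling: str):
        p1, X1 = _predict(fit, data_hi)
        p0, X0 = _predict(fit, data_lo)
        ame = float(np.average(p1 - p0, weights=w) * 100.0)
        grad = np.average(
            (p1 * (1 - p1))[:, None] * X1 - (p0 * (1 - p0))[:, None] * X0, axis=0, weights=w
        ) * 100.0
        se = float(np.sqrt(grad @ V @ grad))
        p_val = float(2 * norm.sf(abs(ame) / se)) if se > 0 else float("nan")
        results.append(
            MarginalEffect(
                variable=variable,
                level=level,
                effect_pp=ame,
                se_pp=se,
                ci_low=ame - z * se,
                ci_high=ame + z * se,
                p_value=p_val,
                scaling=scaling,
            )
        )

    if _is_categorical(data[variable]):
        ref = REFERENCE_LEVELS.get(variable)
        levels = list(pd.unique(data[variable].astype(str)))
        if ref is None:
            ref = sorted(levels)[0]
        lo = data.copy()
        lo[variable] = ref
        for level in [l for l in levels if l != ref]:
            hi = data.copy()
            hi[variable] = level
            _one(hi, lo, level, "discrete_from_reference")
    else:
        sd = _weighted_sd(data[variable].to_numpy(dtype=float), w)
        hi = data.copy()
        hi[variable] = hi[variable] + sd
        _one(hi, data, None, "per_sd_above_mean")
    return results


def _exposure_rows(fit: ModelFit, exposure: str) -> pd.DataFrame:
    """Rows of the OR table belonging to the exposure term."""
    ors = fit.odds_ratios()
    mask = [name.startswith(f"C({exposure},") or name == exposure for name in ors.index]
    return ors.loc[mask]


@dataclass
class AssociationResults:
    """Tidy association and marginal-effect tables for a full run."""

    associations: pd.DataFrame
    marginal_effects: pd.DataFrame
    fits: dict[tuple, ModelFit] = field(default_factory=dict)


def run_association_suite(
    table: pd.DataFrame,
    outcomes: Sequence[str] = ("mdd_met", "mmf_met"),
    exposures: Sequence[str] = DEFAULT_EXPOSURES,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    weight_col: str = "weight",
    cluster_col: str = "cluster_id",
    round_col: str = "round",
    pooled_weighted: bool = True,
    keep_fits: bool = False,
) -> AssociationResults:
    """Crude and adjusted per-round models, pooled random-intercept models
    and marginal effects for every outcome x exposure pair.

    Rounds in which an outcome is entirely missing (recall items not
    collected) are emitted as unavailable rows rather than fitted.
    """
    rounds = sorted(table[round_col].astype(str).unique())
    assoc_rows: list[dict] = []
    ame_rows: list[dict] = []
    fits: dict[tuple, ModelFit] = {}

    def record(fit: ModelFit, outcome: str, exposure: str, rnd: str, model_label: str) -> None:
        for term, row in _exposure_rows(fit, exposure).iterrows():
            assoc_rows.append(
                {
                    "outcome": outcome,
                    "exposure": exposure,
                    "term": term,
                    "round": rnd,
                    "model": model_label,
                    "odds_ratio": row.odds_ratio,
                    "ci_low": row.ci_low,
                    "ci_high": row.ci_high,
                    "p_value": row.p_value,
                    "stars": significance_stars(row.p_value),
                    "n": fit.n,
                    "sigma_u": fit.sigma_u,
                    "available": True,
                    "flags": ";".join(fit.flags),
                }
            )

    def unavailable(outcome: str, exposure: str, rnd: str, model_label: str) -> None:
        assoc_rows.append(
            {
                "outcome": outcome,
                "exposure": exposure,
                "term": None,
                "round": rnd,
                "model": model_label,
                "odds_ratio": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p_value": np.nan,
                "stars": "",
                "n": 0,
                "sigma_u": None,
                "available": False,
                "flags": "outcome_not_collected",
            }
        )

    for outcome in outcomes:
        available_rounds = [
            r for r in rounds if table.loc[table[round_col].astype(str) == r, outcome].notna().any()
        ]
        for exposure in exposures:
            for rnd in rounds:
                sub = table[table[round_col].astype(str) == rnd]
                if rnd not in available_rounds:
                    unavailable(outcome, exposure, rnd, "crude")
                    unavailable(outcome, exposure, rnd, "adjusted")
                    continue
                crude = fit_weighted_logistic(
                    sub, outcome, exposure, (), weight_col=weight_col, cluster_col=cluster_col
                )
                record(crude, outcome, exposure, rnd, "crude")
                adjusted = fit_weighted_logistic(
                    sub, outcome, exposure, covariates, weight_col=weight_col, cluster_col=cluster_col
                )
                record(adjusted, outcome, exposure, rnd, "adjusted")
                if keep_fits:
                    fits[(outcome, exposure, rnd, "crude")] = crude
                    fits[(outcome, exposure, rnd, "adjusted")] = adjusted
            pooled_tab = table[table[round_col].astype(str).isin(available_rounds)]
            pooled = fit_random_intercept_logistic(
                pooled_tab,
                outcome,
                exposure,
                covariates,
                group_col=round_col,
                weight_col=weight_col if pooled_weighted else None,
            )
            record(pooled, outcome, exposure, "pooled", "adjusted")
            fits[(outcome, exposure, "pooled", "adjusted")] = pooled
            for me in average_marginal_effect(pooled, exposure):
                ame_rows.append(
                    {
                        "outcome": outcome,
                        "exposure": exposure,
                        "level": me.level,
                        "effect_pp": me.effect_pp,
                        "se_pp": me.se_pp,
                        "ci_low": me.ci_low,
                        "ci_high": me.ci_high,
                        "p_value": me.p_value,
                        "stars": significance_stars(me.p_value),
                        "scaling": me.scaling,
                    }
                )

    return AssociationResults(
        associations=pd.DataFrame(assoc_rows),
        marginal_effects=pd.DataFrame(ame_rows),
        fits=fits,
    )
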