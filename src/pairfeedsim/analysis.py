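"""The four per-trial analysis models and their treatment-effect p-values.

Outcome: total weight change dW per animal. Treatment is coded
non-pair-fed = 0, pair-fed = 1, so beta1 is the pf-minus-non-pf effect.

* crude_lm            — OLS of dW on the treatment indicator.
* adjusted_lm         — OLS adding the within-animal mean daily food intake
                        (the average realized intake over study days 1..n,
                        baseline excluded) as a covariate.
* pair_lmm            — linear mixed model, treatment fixed, random
                        intercept per weight-rank pair (individual design).
* pair_lmm_adjusted   — pair_lmm plus the intake covariate as fixed effect.

OLS p-values come from the usual t distribution (residual df). Mixed-model
p-values use a Wald t statistic whose df is, by default, a Satterthwaite
approximation computed from the REML observed information (statsmodels'
MixedLM reports normal-based p-values only, which are anti-conservative at
small m); ``df_method="residual"`` switches to n_obs - rank(X).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .designs import IntakeMatrix, PairAssignment

CRUDE_LM = "crude_lm"
ADJUSTED_LM = "adjusted_lm"
PAIR_LMM = "pair_lmm"
PAIR_LMM_ADJUSTED = "pair_lmm_adjusted"
ALL_MODELS = (CRUDE_LM, ADJUSTED_LM, PAIR_LMM, PAIR_LMM_ADJUSTED)

_VAR_TINY = 1e-12


@dataclasses.dataclass
class ModelFit:
    """Treatment-coefficient summary from one fitted model."""

    model_tag: str
    beta1: float
    se: float
    p_value: float
    df: float
    flag: str | None = None  # degenerate/fallback marker, never silently dropped

    @property
    def converged(self) -> bool:
        return self.flag is None


@dataclasses.dataclass
class TrialPValues:
    """Treatment p-values from every model fitted to one simulated trial."""

    iteration: int
    fits: dict[str, ModelFit]
    mean_intake_diff: float  # pf minus non-pf group mean of within-animal means

    @property
    def p_crude(self) -> float | None:
        return self._p(CRUDE_LM)

    @property
    def p_adjusted(self) -> float | None:
        return self._p(ADJUSTED_LM)

    @property
    def p_pair_lmm(self) -> float | None:
        return self._p(PAIR_LMM)

    @property
    def p_pair_lmm_adjusted(self) -> float | None:
        return self._p(PAIR_LMM_ADJUSTED)

    def _p(self, tag: str) -> float | None:
        fit = self.fits.get(tag)
        return None if fit is None else fit.p_value


def compute_within_animal_mean_intake(intakes: IntakeMatrix) -> np.ndarray:
    """Mean realized intake over study days 1..n (baseline day excluded)."""
    return intakes.realized.mean(axis=1)


# ----------------------------------------------------------------------
# OLS models
# ----------------------------------------------------------------------

def _design_matrix(is_pf: np.ndarray, covariate: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(is_pf.size), is_pf.astype(float)]
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=float))
    return np.column_stack(cols)


def _degenerate_outcome(outcome: np.ndarray, is_pf: np.ndarray) -> bool:
    return (
        float(np.var(outcome[is_pf])) <= _VAR_TINY
        and float(np.var(outcome[~is_pf])) <= _VAR_TINY
    )


def fit_crude_lm(outcome: np.ndarray, is_pf: np.ndarray) -> ModelFit:
    """OLS of the outcome on the treatment indicator (2m - 2 residual df)."""
    outcome = np.asarray(outcome, dtype=float)
    is_pf = np.asarray(is_pf, dtype=bool)
    if is_pf.sum() < 2 or (~is_pf).sum() < 2:
        raise ValueError("crude model needs at least 2 animals per group")
    beta1 = float(outcome[is_pf].mean() - outcome[~is_pf].mean())
    if _degenerate_outcome(outcome, is_pf):
        return ModelFit(CRUDE_LM, beta1, np.nan, 1.0, outcome.size - 2.0,
                        flag="degenerate_outcome")
    res = sm.OLS(outcome, _design_matrix(is_pf, None)).fit()
    return ModelFit(CRUDE_LM, float(res.params[1]), float(res.bse[1]),
                    float(res.pvalues[1]), float(res.df_resid))


def fit_adjusted_lm(
    outcome: np.ndarray, is_pf: np.ndarray, covariate: np.ndarray
) -> ModelFit:
    """OLS with the within-animal mean intake covariate (2m - 3 residual df).

    A zero-variance covariate is collinear with the intercept; the fit then
    falls back to the crude model and is flagged.
    """
    outcome = np.asarray(outcome, dtype=float)
    is_pf = np.asarray(is_pf, dtype=bool)
    covariate = np.asarray(covariate, dtype=float)
    if float(np.var(covariate)) <= _VAR_TINY:
        fallback = fit_crude_lm(outcome, is_pf)
        return dataclasses.replace(fallback, model_tag=ADJUSTED_LM, flag="constant_covariate")
    res = sm.OLS(outcome, _design_matrix(is_pf, covariate)).fit()
    p = float(res.pvalues[1])
    flag = None
    if not np.isfinite(p):  # outcome exactly explained by the covariate
        p, flag = 1.0, "degenerate_fit"
    return ModelFit(ADJUSTED_LM, float(res.params[1]), float(res.bse[1]),
                    p, float(res.df_resid), flag=flag)


# ----------------------------------------------------------------------
# Mixed models with a pair random intercept
# ----------------------------------------------------------------------

def _reml_neglog(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                 same_pair: np.ndarray) -> float:
    """Negative REML log-likelihood of the random-intercept model (up to const).

    theta = (sigma_e^2, sigma_b^2); V = s2e * I + s2b * same_pair.
    """
    n = y.size
    V = theta[0] * np.eye(n) + theta[1] * same_pair
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return 0.5 * (logdet_v + logdet_x + float(r @ Vi @ r))


def _gls_var_beta(theta: np.ndarray, X: np.ndarray, same_pair: np.ndarray,
                  idx: int) -> float:
    n = X.shape[0]
    V = theta[0] * np.eye(n) + theta[1] * same_pair
    Vi = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vi @ X)
    return float(C[idx, idx])


def satterthwaite_df(
    y: np.ndarray,
    X: np.ndarray,
    pair_ids: np.ndarray,
    sigma2_e: float,
    sigma2_b: float,
    coef_idx: int,
) -> float:
    """Satterthwaite df for one fixed-effect coefficient of a pair-intercept LMM.

    df = 2 * phi^2 / (g' A g) with phi(theta) the GLS variance of the
    coefficient, g its gradient in theta = (sigma_e^2, sigma_b^2), and A the
    inverse observed REML information, all evaluated at the REML estimates.
    Gradient and Hessian are central finite differences (the matrices are at
    most 2m x 2m, so exact dense algebra is cheap). At the sigma_b^2 = 0
    boundary the model is OLS and the residual df is returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    pair_ids = np.asarray(pair_ids)
    n, rank = X.shape
    resid_df = float(n - rank)
    if not (sigma2_e > 0) or sigma2_b <= max(_VAR_TINY, 1e-6 * sigma2_e):
        return resid_df
    same_pair = (pair_ids[:, None] == pair_ids[None, :]).astype(float)
    theta = np.array([sigma2_e, sigma2_b], dtype=float)

    phi0 = _gls_var_beta(theta, X, same_pair, coef_idx)
    h = 1e-4 * theta
    grad = np.empty(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        grad[i] = (
            _gls_var_beta(theta + e, X, same_pair, coef_idx)
            - _gls_var_beta(theta - e, X, same_pair, coef_idx)
        ) / (2 * h[i])

    def f(t: np.ndarray) -> float:
        return _reml_neglog(t, y, X, same_pair)

    hh = 1e-3 * theta
    H = np.empty((2, 2))
    f0 = f(theta)
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = hh[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / hh[i] ** 2
    e0 = np.array([hh[0], 0.0])
    e1 = np.array([0.0, hh[1]])
    H[0, 1] = H[1, 0] = (
        f(theta + e0 + e1) - f(theta + e0 - e1) - f(theta - e0 + e1) + f(theta - e0 - e1)
    ) / (4 * hh[0] * hh[1])

    try:
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return resid_df
    denom = float(grad @ A @ grad)
    if not np.isfinite(denom) or denom <= 0:
        return resid_df
    df = 2.0 * phi0 ** 2 / denom
    if not np.isfinite(df) or df < 1.0:
        return resid_df
    return df


def _ols_boundary_fallback(
    outcome: np.ndarray, X: np.ndarray, tag: str, flag: str
) -> ModelFit:
    """Refit with the pair variance at its zero boundary, i.e. plain OLS."""
    res = sm.OLS(outcome, X).fit()
    p = float(res.pvalues[1])
    if not np.isfinite(p):
        p = 1.0
    return ModelFit(tag, float(res.params[1]), float(res.bse[1]), p,
                    float(res.df_resid), flag=flag)


def _fit_lmm(
    outcome: np.ndarray,
    is_pf: np.ndarray,
    pairs: PairAssignment,
    animal_id: np.ndarray,
    covariate: np.ndarray | None,
    tag: str,
    df_method: str = "satterthwaite",
) -> ModelFit:
    outcome = np.asarray(outcome, dtype=float)
    is_pf = np.asarray(is_pf, dtype=bool)
    if pairs is None:
        raise ValueError("pair random-effect models require a PairAssignment")
    flag = None
    if covariate is not None and float(np.var(covariate)) <= _VAR_TINY:
        covariate = None
        flag = "constant_covariate"
    X = _design_matrix(is_pf, covariate)
    pair_ids = pairs.pair_rank_of(animal_id)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(outcome, X, groups=pair_ids).fit(reml=True)
            beta1 = float(res.fe_params[1])
            se = float(res.bse_fe[1])
            s2e = float(res.scale)
            s2b = float(np.asarray(res.cov_re).ravel()[0])
        ok = np.isfinite(beta1) and np.isfinite(se) and se > 0
    except Exception:
        ok = False
    if not ok:
        return _ols_boundary_fallback(outcome, X, tag, flag="lmm_boundary_fallback")

    if df_method == "satterthwaite":
        df = satterthwaite_df(outcome, X, pair_ids, s2e, s2b, coef_idx=1)
    else:
        df = float(outcome.size - X.shape[1])
    t = beta1 / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ModelFit(tag, beta1, se, p, df, flag=flag)


def fit_pair_lmm(
    outcome: np.ndarray,
    is_pf: np.ndarray,
    pairs: PairAssignment,
    animal_id: np.ndarray,
    df_method: str = "satterthwaite",
) -> ModelFit:
    """Mixed model: treatment fixed effect, random intercept per pair."""
    return _fit_lmm(outcome, is_pf, pairs, animal_id, None, PAIR_LMM, df_method)


def fit_pair_lmm_adjusted(
    outcome: np.ndarray,
    is_pf: np.ndarray,
    pairs: PairAssignment,
    animal_id: np.ndarray,
    covariate: np.ndarray,
    df_method: str = "satterthwaite",
) -> ModelFit:
    """Pair random-intercept mixed model with the intake covariate."""
    return _fit_lmm(outcome, is_pf, pairs, animal_id, covariate, PAIR_LMM_ADJUSTED, df_method)
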