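"""Nested additive logistic prediction models.

The study design compares three nested models of post-induction
hypotension risk:

* ``M0``    — clinical covariates screened by L1-penalised (LASSO)
  logistic regression with cross-validated lambda at the 1-SE rule;
* ``Mecho`` — M0 plus echocardiographic measurements;
* ``Mfull`` — Mecho plus the ventriculo-arterial coupling block
  (continuous Ea and Ees, and the Ea/Ees > 1 flag).

Each model is a binomial generalised additive model (logit link):
categorical/binary terms enter parametrically as log odds ratios,
continuous terms as penalised B-spline smooths whose smoothing
parameters are chosen per term by minimising the effective-dof-corrected
AIC.  The effective degrees of freedom (edf) are the trace of the hat
matrix, so a heavily penalised smooth counts for little more than a
linear term; likelihood-ratio chi-square statistics against the null use
the unpenalised log-likelihood at the penalised fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.gam.api import BSplines, GLMGam

from .errors import ConfigError, ConvergenceError, DomainError

__all__ = [
    "ModelSpec",
    "FittedAdditiveModel",
    "LassoConfig",
    "lasso_select",
    "fit_additive_logistic",
    "partial_effect",
    "PartialEffect",
]


# --------------------------------------------------------------------------
# LASSO screening
# --------------------------------------------------------------------------

@dataclass
class LassoConfig:
    """Settings for the L1 screening stage."""

    n_folds: int = 10
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    seed: int = 0
    fixed_lambda: float | None = None  # bypass CV at this penalty
    max_iter: int = 5000


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))


def _l1_fit(X: np.ndarray, y: np.ndarray, lam: float, seed: int, max_iter: int):
    # saga leaves the intercept unpenalised, matching the glmnet convention
    C = 1.0 / (len(y) * lam)
    clf = LogisticRegression(
        penalty="l1", C=C, solver="saga", max_iter=max_iter,
        tol=1e-5, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def lasso_select(
    cohort: pd.DataFrame,
    candidates: list[str],
    config: LassoConfig | None = None,
    outcome: str = "pih",
) -> list[str]:
    """Names of candidates with non-zero LASSO coefficients.

    Candidates are standardised, a geometric lambda path is walked from
    the smallest all-zero penalty downward, out-of-fold binomial deviance
    is averaged over stratified K folds, and the penalty is fixed at the
    1-SE rule (largest lambda whose CV deviance is within one standard
    error of the minimum).  Deterministic given ``config.seed``.
    """
    config = config or LassoConfig()
    if len(candidates) < 2:
        raise ConfigError("need at least 2 LASSO candidates")
    missing = [c for c in candidates if c not in cohort.columns]
    if missing:
        raise ConfigError(f"candidates not in cohort: {missing}")
    y = cohort[outcome].to_numpy(dtype=float)
    X = cohort[candidates].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise DomainError("missing values among LASSO candidates; impute first")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    n = len(y)
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n

    if config.fixed_lambda is not None:
        lam_1se = config.fixed_lambda
    else:
        lams = np.geomspace(lam_max, lam_max * config.lambda_min_ratio,
                            config.n_lambda)
        folds = StratifiedKFold(config.n_folds, shuffle=True,
                                random_state=config.seed)
        dev = np.zeros((config.n_folds, config.n_lambda))
        for f, (tr, te) in enumerate(folds.split(Xs, y)):
            for j, lam in enumerate(lams):
                clf = _l1_fit(Xs[tr], y[tr], lam, config.seed, config.max_iter)
                dev[f, j] = _binomial_deviance(y[te], clf.predict_proba(Xs[te])[:, 1])
        mean_dev = dev.mean(axis=0)
        se_dev = dev.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
        j_min = int(np.argmin(mean_dev))
        threshold = mean_dev[j_min] + se_dev[j_min]
        # lambdas are ordered large -> small; take the largest within 1 SE
        j_1se = int(np.nonzero(mean_dev <= threshold)[0][0])
        lam_1se = lams[j_1se]

    clf = _l1_fit(Xs, y, lam_1se, config.seed, config.max_iter)
    coef = clf.coef_.ravel()
    selected = [c for c, b in zip(candidates, coef) if abs(b) > 1e-8]
    if not selected:
        warnings.warn(
            "LASSO selected no variables; the clinical model degenerates "
            "to an intercept", stacklevel=2,
        )
    return selected


# --------------------------------------------------------------------------
# Penalised additive logistic models
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Terms of one additive logistic model."""

    name: str
    parametric_terms: list[str] = field(default_factory=list)
    smooth_terms: list[str] = field(default_factory=list)
    basis_df: int = 10
    parent: str | None = None

    def all_terms(self) -> list[str]:
        return list(self.parametric_terms) + list(self.smooth_terms)

    def drop(self, term: str) -> "ModelSpec":
        """Copy of the spec without one term (for drop-one refits)."""
        if term in self.parametric_terms:
            return replace(self, name=f"{self.name}-{term}",
                           parametric_terms=[t for t in self.parametric_terms
                                             if t != term])
        if term in self.smooth_terms:
            return replace(self, name=f"{self.name}-{term}",
                           smooth_terms=[t for t in self.smooth_terms
                                         if t != term])
        raise ConfigError(f"term {term!r} not in model {self.name!r}")


@dataclass
class FittedAdditiveModel:
    """A fitted additive logistic model with its information summary."""

    spec: ModelSpec
    params: np.ndarray
    cov_params: np.ndarray
    edf: float  # total effective degrees of freedom (incl. intercept)
    edf_by_column: np.ndarray
    llf: float  # unpenalised log-likelihood at the penalised fit
    llf_null: float
    lr_chisq: float  # 2 * (llf - llf_null)
    fitted: np.ndarray  # per-patient probabilities
    alpha: list[float]  # smoothing parameters per smooth term
    column_names: list[str]
    parametric_levels: dict  # term -> (reference level, other levels)
    _smoother: object = None
    _train_frame: object = None

    def coefficient(self, term: str) -> float:
        """Parametric coefficient (log-OR) of a binary/categorical term."""
        try:
            idx = self.column_names.index(term)
        except ValueError as exc:
            raise ConfigError(f"{term!r} has no parametric coefficient") from exc
        return float(self.params[idx])


def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        raise DomainError("outcome has a single class")
    n1 = y.sum()
    n0 = len(y) - n1
    return n1 * np.log(p) + n0 * np.log(1 - p)


def _manual_llf(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _build_parametric(cohort: pd.DataFrame, terms: list[str]):
    """Design columns for categorical/binary terms.

    Object/categorical columns are dummy-coded against their most
    frequent level; numeric columns are taken as-is.
    """
    cols, names = [], []
    levels: dict = {}
    for t in terms:
        s = cohort[t]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            counts = s.value_counts()
            ref = counts.index[0]
            others = [l for l in counts.index if l != ref]
            levels[t] = (ref, others)
            for lev in others:
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{t}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(t)
    return cols, names, levels


def _fit_gam(y, exog, smoother, alpha):
    if smoother is None:
        model = sm.GLM(y, exog, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        edf_by_col = np.ones(exog.shape[1])
        return res, edf_by_col
    model = GLMGam(y, exog=exog, smoother=smoother, alpha=alpha,
                   family=sm.families.Binomial())
    res = model.fit(maxiter=200, tol=1e-9)
    return res, np.asarray(res.edf)


def _select_alpha(y, exog, smoother, n_terms, passes=2):
    """Per-smooth alpha by coordinate descent on AIC = -2 llf + 2 edf."""
    alpha = [1.0] * n_terms

    def aic_at(log10_a, idx):
        trial = list(alpha)
        trial[idx] = 10.0 ** log10_a
        try:
            res, edf = _fit_gam(y, exog, smoother, trial)
        except Exception:
            return np.inf
        return -2.0 * res.llf + 2.0 * float(np.sum(edf))

    for _ in range(passes):
        for idx in range(n_terms):
            opt = minimize_scalar(aic_at, bounds=(-3.0, 7.0), args=(idx,),
                                  method="bounded",
                                  options={"xatol": 0.05, "maxiter": 25})
            alpha[idx] = 10.0 ** float(opt.x)
    return alpha


def fit_additive_logistic(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    outcome: str = "pih",
    alpha: list[float] | None = None,
) -> FittedAdditiveModel:
    """Fit one additive logistic model.

    ``alpha`` overrides smoothing-parameter selection (used by bootstrap
    refits); otherwise each smooth's penalty is selected by AIC.
    """
    for t in spec.all_terms() + [outcome]:
        if t not in cohort.columns:
            raise ConfigError(f"model {spec.name!r}: column {t!r} missing")
    sub = cohort[spec.all_terms() + [outcome]]
    if sub.isna().any().any():
        raise DomainError(
            "missing values in model columns; imputation happens upstream"
        )
    y = cohort[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DomainError("outcome has a single class")

    par_cols, par_names, levels = _build_parametric(cohort, spec.parametric_terms)
    exog = np.column_stack([np.ones(len(y))] + par_cols) if par_cols else \
        np.ones((len(y), 1))
    names = ["const"] + par_names

    smoother = None
    if spec.smooth_terms:
        smoother = BSplines(
            cohort[spec.smooth_terms],
            df=[spec.basis_df] * len(spec.smooth_terms),
            degree=[3] * len(spec.smooth_terms),
        )
        if alpha is None:
            alpha = _select_alpha(y, exog, smoother, len(spec.smooth_terms))
        names = names + list(smoother.col_names)
    else:
        alpha = []

    res, edf_by_col = _fit_gam(y, exog, smoother, alpha)
    fitted = np.asarray(res.predict())
    if np.all((fitted > 1 - 1e-8) == (y == 1)) and np.all(
            (fitted < 1e-8) == (y == 0)):
        raise ConvergenceError(
            f"model {spec.name!r}: complete separation; increase penalisation "
            "or drop the offending term"
        )
    llf = _manual_llf(y, fitted)
    llf_null = _null_llf(y)
    return FittedAdditiveModel(
        spec=spec,
        params=np.asarray(res.params, dtype=float),
        cov_params=np.asarray(res.cov_params(), dtype=float),
        edf=float(np.sum(edf_by_col)),
        edf_by_column=edf_by_col,
        llf=llf,
        llf_null=llf_null,
        lr_chisq=max(0.0, 2.0 * (llf - llf_null)),
        fitted=fitted,
        alpha=list(alpha),
        column_names=names,
        parametric_levels=levels,
        _smoother=smoother,
        _train_frame=cohort[spec.all_terms()],
    )


@dataclass
class PartialEffect:
    """Centred log-odds contribution of one model term on a grid."""

    variable: str
    grid: np.ndarray
    effect: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def partial_effect(
    model: FittedAdditiveModel, variable: str, grid=None
) -> PartialEffect:
    """Log-odds contribution of ``variable``.

    Smooth terms return the spline contribution over ``grid``, centred to
    mean zero over the grid, with pointwise normal 95% intervals.
    Categorical/binary terms return the step function of their raw
    coefficients (reference level at zero).
    """
    spec = model.spec
    if variable in spec.parametric_terms:
        if variable in model.parametric_levels:
            ref, others = model.parametric_levels[variable]
            grid_ = np.array([ref] + others, dtype=object)
            idx = [model.column_names.index(f"{variable}[{l}]") for l in others]
        else:
            grid_ = np.array([0.0, 1.0])
            idx = [model.column_names.index(variable)]
        eff = np.concatenate([[0.0], model.params[idx]])
        se = np.concatenate([[0.0], np.sqrt(np.diag(model.cov_params)[idx])])
        return PartialEffect(variable, grid_, eff, se,
                             eff - 1.96 * se, eff + 1.96 * se)

    if variable not in spec.smooth_terms:
        raise ConfigError(f"{variable!r} is not a term of model {spec.name!r}")

    k = spec.smooth_terms.index(variable)
    smoother = model._smoother.smoothers[k]
    if grid is None:
        x = model._train_frame[variable].to_numpy(dtype=float)
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)
    basis = smoother.transform(grid)
    if basis.ndim == 1:
        basis = basis[None, :]
    start = len(model.column_names) - sum(
        s.dim_basis for s in model._smoother.smoothers
    )
    offset = start + sum(
        model._smoother.smoothers[j].dim_basis for j in range(k)
    )
    idx = np.arange(offset, offset + smoother.dim_basis)
    contrib = basis @ model.params[idx]
    centred = contrib - contrib.mean()
    center_mat = basis - basis.mean(axis=0, keepdims=True)
    cov = model.cov_params[np.ix_(idx, idx)]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", center_mat, cov,
                                      center_mat), 0.0))
    return PartialEffect(variable, grid, centred, se,
                         centred - 1.96 * se, centred + 1.96 * se)
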