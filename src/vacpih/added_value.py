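"""Incremental predictive value of nested risk models.

Implements the added-value toolkit used to compare the nested models:

* **FNI** — fraction of new information, the adequacy complement
  ``1 - LR_chisq(reduced) / LR_chisq(full)``: the share of the full
  model's likelihood-ratio information that the reduced model misses.
  For a nested chain the adequacies multiply, so sequential FNIs compose
  as ``1 - FNI_total = (1 - FNI_step1) * (1 - FNI_step2)``.
* **Likelihood-ratio comparison p** — upper-tail chi-square probability
  of the deviance difference at a possibly non-integer df (effective-dof
  differences of penalised additive models).
* **AUC / DeLong** — Mann-Whitney AUC with midrank tie handling, and the
  DeLong placement-value test for the difference of two correlated AUCs
  evaluated on the same patients.
* **Holm** — step-down familywise adjustment over one test family.
* **Bootstrap contribution decomposition** — per-term drop-one
  likelihood-ratio chi-square shares of the full model, normalised to
  100%, with percentile bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, NestingError
from .models import FittedAdditiveModel, ModelSpec, fit_additive_logistic

__all__ = [
    "fni",
    "fni_compose",
    "comparison_p",
    "auc",
    "delong_compare",
    "DeLongResult",
    "holm_adjust",
    "NestedComparison",
    "compare_nested",
    "ContributionTable",
    "explained_variance_contributions",
]


def fni(lr_reduced: float, lr_full: float) -> float:
    """Fraction of new information, ``1 - lr_reduced / lr_full``."""
    if lr_full <= 0:
        raise DomainError("FNI undefined: full-model LR chi-square must be > 0")
    if lr_reduced < 0:
        raise DomainError("LR chi-square cannot be negative")
    if lr_reduced > lr_full:
        raise NestingError(
            f"nesting violation: reduced LR {lr_reduced:.4g} exceeds full "
            f"LR {lr_full:.4g}"
        )
    return 1.0 - lr_reduced / lr_full


def fni_compose(fni_first: float, fni_second: float) -> float:
    """Total FNI across two sequential nested steps.

    Adequacies (1 - FNI) multiply along a nested chain, so
    ``1 - total = (1 - first) * (1 - second)``.
    """
    for v in (fni_first, fni_second):
        if not 0 <= v <= 1:
            raise DomainError(f"FNI must be in [0,1], got {v!r}")
    return 1.0 - (1.0 - fni_first) * (1.0 - fni_second)


def comparison_p(deviance: float, df: float) -> float:
    """Upper-tail chi-square probability at possibly non-integer df."""
    if deviance < 0:
        raise DomainError(f"deviance must be >= 0, got {deviance!r}")
    if df <= 0:
        raise DomainError(f"df must be > 0, got {df!r}")
    return float(stats.chi2.sf(deviance, df))


def auc(scores, labels) -> float:
    """Mann-Whitney AUC; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DomainError("both outcome classes must be present")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (midrank formulation)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = rankdata(np.concatenate([pos, neg]))
    pos_r = rankdata(pos)
    neg_r = rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n  # per positive subject
    v01 = 1.0 - (all_r[m:] - neg_r) / m  # per negative subject
    a = v10.mean()
    return a, v10, v01


@dataclass
class DeLongResult:
    """Paired comparison of two AUCs on the same patients."""

    auc_a: float
    auc_b: float
    delta: float  # auc_a - auc_b
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float


def delong_compare(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must refer to the same patients in the same
    order.  Identical score vectors return delta 0 with p = 1 by
    convention; a degenerate zero variance with a non-zero delta raises.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise DomainError("scores_a, scores_b and labels must align")
    a_a, v10_a, v01_a = _placements(scores_a, labels)
    a_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    delta = a_a - a_b
    if np.array_equal(scores_a, scores_b):
        return DeLongResult(a_a, a_b, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if abs(delta) < 1e-12:
            return DeLongResult(a_a, a_b, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0)
        raise DomainError("degenerate DeLong variance with non-zero delta")
    se = float(np.sqrt(var))
    z = delta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(a_a, a_b, float(delta), se, float(z), p,
                        float(delta - 1.96 * se), float(delta + 1.96 * se))


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


@dataclass
class NestedComparison:
    """Added-value summary for one reduced/full model pair."""

    reduced: str
    full: str
    deviance: float  # lr_chisq(full) - lr_chisq(reduced)
    df: float  # edf(full) - edf(reduced)
    p_lr: float
    fni: float
    auc_reduced: float
    auc_full: float
    delta_auc: float
    delta_auc_ci: tuple[float, float]
    p_delong: float
    p_lr_holm: float | None = None
    p_delong_holm: float | None = None


def compare_nested(
    reduced: FittedAdditiveModel,
    full: FittedAdditiveModel,
    labels,
) -> NestedComparison:
    """Deviance, FNI and DeLong AUC comparison for a nested pair."""
    deviance = full.lr_chisq - reduced.lr_chisq
    if deviance < -1e-6:
        raise NestingError(
            f"{full.spec.name!r} fits worse than nested {reduced.spec.name!r} "
            f"(deviance {deviance:.4g})"
        )
    deviance = max(deviance, 0.0)
    df = max(full.edf - reduced.edf, 1e-8)
    dl = delong_compare(full.fitted, reduced.fitted, np.asarray(labels))
    return NestedComparison(
        reduced=reduced.spec.name,
        full=full.spec.name,
        deviance=deviance,
        df=df,
        p_lr=comparison_p(deviance, df),
        fni=fni(reduced.lr_chisq, full.lr_chisq),
        auc_reduced=dl.auc_b,
        auc_full=dl.auc_a,
        delta_auc=dl.delta,
        delta_auc_ci=(dl.ci_low, dl.ci_high),
        p_delong=dl.p,
    )


@dataclass
class ContributionTable:
    """Drop-one relative-explained-variance shares with bootstrap CIs."""

    table: pd.DataFrame  # columns: term, percent, ci_low, ci_high
    B: int


def _contribution_point(cohort, spec, outcome, fitted_full=None,
                        fixed_alphas=None):
    """Per-term drop-one LR chi-square, plus each submodel's alphas."""
    full = fitted_full or fit_additive_logistic(cohort, spec, outcome=outcome)
    drops, alphas = {}, {}
    for term in spec.all_terms():
        sub_spec = spec.drop(term)
        alpha = None if fixed_alphas is None else fixed_alphas.get(term)
        sub = fit_additive_logistic(cohort, sub_spec, outcome=outcome,
                                    alpha=alpha)
        drops[term] = max(full.lr_chisq - sub.lr_chisq, 0.0)
        alphas[term] = sub.alpha
    return full, drops, alphas


def _normalise(drops: dict[str, float]) -> dict[str, float]:
    total = sum(drops.values())
    if total <= 0:
        # no term carries information; spread evenly so shares still sum to 100
        return {t: 100.0 / len(drops) for t in drops}
    return {t: 100.0 * v / total for t, v in drops.items()}


def explained_variance_contributions(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    B: int = 2000,
    seed: int = 0,
    outcome: str = "pih",
    fitted_full: FittedAdditiveModel | None = None,
) -> ContributionTable:
    """Relative explained-variance share of each full-model term.

    The point estimate drops each term in turn, refits (re-selecting its
    smoothing parameters), and normalises the per-term likelihood-ratio
    chi-square losses to sum to 100%.  Confidence intervals are 2.5/97.5
    percentiles over ``B`` patient-level bootstrap resamples; bootstrap
    refits reuse the point estimate's smoothing parameters to keep the
    replicate-level optimisation deterministic and tractable.
    """
    if B < 1:
        raise DomainError(f"B must be >= 1, got {B!r}")
    full, drops, sub_alphas = _contribution_point(
        cohort, spec, outcome, fitted_full=fitted_full)
    point = _normalise(drops)
    terms = list(point)

    rng = np.random.default_rng(seed)
    n = len(cohort)
    boot = np.empty((B, len(terms)))
    for b in range(B):
        idx = rng.integers(0, n, n)
        sample = cohort.iloc[idx].reset_index(drop=True)
        # a resample can lose an outcome class only for tiny cohorts; redraw
        tries = 0
        while sample[outcome].nunique() < 2:
            idx = rng.integers(0, n, n)
            sample = cohort.iloc[idx].reset_index(drop=True)
            tries += 1
            if tries > 100:
                raise DomainError("bootstrap cannot find both outcome classes")
        bfull = fit_additive_logistic(sample, spec, outcome=outcome,
                                      alpha=full.alpha)
        bdrops = {}
        for term in terms:
            bsub = fit_additive_logistic(sample, spec.drop(term),
                                         outcome=outcome,
                                         alpha=sub_alphas[term])
            bdrops[term] = max(bfull.lr_chisq - bsub.lr_chisq, 0.0)
        bnorm = _normalise(bdrops)
        boot[b] = [bnorm[t] for t in terms]

    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    table = pd.DataFrame({
        "term": terms,
        "percent": [point[t] for t in terms],
        "ci_low": lo,
        "ci_high": hi,
    })
    return ContributionTable(table=table, B=B)
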