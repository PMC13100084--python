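"""Group-comparison descriptive statistics ("Table 1 / Table 2" style).

Routing rules for comparing a variable between outcome groups:

* continuous — Shapiro-Wilk normality in **both** groups at alpha 0.05
  routes to Welch's t-test (summarised mean +/- SD); otherwise to the
  Wilcoxon rank-sum test (median [IQR]);
* categorical — Pearson chi-square without continuity correction,
  switching to Fisher's exact test when any expected cell count is
  below 5 (r x c tables use a seeded Monte-Carlo exact test).

Data-hygiene helpers implement the cohort's pre-modelling rules: median
imputation of sparsely missing global longitudinal strain, and exclusion
of binary covariates with fewer than five observations in either outcome
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = [
    "GroupComparison",
    "compare_groups",
    "contingency_p",
    "impute_gls",
    "exclude_sparse_binaries",
    "summary_table",
]

SHAPIRO_ALPHA = 0.05
_FISHER_MC_REPS = 20_000
_FISHER_MC_SEED = 20_240_405


@dataclass(frozen=True)
class GroupComparison:
    """One row of a descriptive comparison table."""

    variable: str
    test: str  # welch | wilcoxon | chi2 | fisher | constant
    summary: dict  # group label -> formatted summary string
    p: float


def _fisher_rxc_mc(table: np.ndarray, reps: int = _FISHER_MC_REPS,
                   seed: int = _FISHER_MC_SEED) -> float:
    """Monte-Carlo Fisher exact p for an r x c table.

    Conditions on both margins by shuffling individual labels; the p is
    the fraction of resampled tables whose probability (equivalently,
    whose chi-square) is at least as extreme as observed.  Seeded for
    reproducibility.
    """
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    obs = stats.chi2_contingency(table, correction=False)[0]
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(cols)
        t = np.zeros_like(table)
        np.add.at(t, (rows, perm), 1)
        with np.errstate(invalid="ignore"):
            s = stats.chi2_contingency(t, correction=False)[0]
        if s >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (reps + 1)


def contingency_p(table) -> tuple[str, float]:
    """Test an r x c contingency table per the routing rules.

    Returns (test name, p).  Pearson chi-square without continuity
    correction; Fisher's exact when any expected count is < 5 (exact for
    2 x 2, seeded Monte-Carlo otherwise).
    """
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        raise DomainError("empty contingency table")
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        if table.shape == (2, 2):
            return "fisher", float(stats.fisher_exact(table)[1])
        return "fisher", _fisher_rxc_mc(table.astype(int))
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi2", float(p)


def _is_categorical(s: pd.Series) -> bool:
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        return True
    vals = s.dropna().unique()
    return len(vals) <= 2 and set(vals) <= {0, 1, 0.0, 1.0, True, False}


def compare_groups(
    cohort: pd.DataFrame, variable: str, outcome: str = "pih"
) -> GroupComparison:
    """Compare one variable between the two outcome groups."""
    if variable not in cohort.columns:
        raise DomainError(f"variable {variable!r} not in cohort")
    y = cohort[outcome]
    groups = sorted(y.dropna().unique())
    if len(groups) != 2:
        raise DomainError(f"outcome {outcome!r} must be binary with both classes")
    s = cohort[variable]
    g0 = s[y == groups[0]].dropna()
    g1 = s[y == groups[1]].dropna()
    if len(g0) == 0 or len(g1) == 0:
        raise DomainError(f"empty outcome group for {variable!r}")

    if _is_categorical(s):
        tab = pd.crosstab(s, y).to_numpy()
        if tab.shape[0] < 2:
            warnings.warn(f"{variable!r} is constant; p set to 1", stacklevel=2)
            test, p = "constant", 1.0
        else:
            test, p = contingency_p(tab)
        summary = {
            str(g): {
                str(lev): f"{int(cnt)} ({100 * cnt / (y == g).sum():.0f})"
                for lev, cnt in s[y == g].value_counts().items()
            }
            for g in groups
        }
        return GroupComparison(variable, test, summary, p)

    if g0.nunique() == 1 and g1.nunique() == 1 and g0.iloc[0] == g1.iloc[0]:
        warnings.warn(f"{variable!r} is constant; p set to 1", stacklevel=2)
        return GroupComparison(variable, "constant",
                               {str(g): f"{g0.iloc[0]:g}" for g in groups}, 1.0)

    normal = all(
        len(g) >= 3 and stats.shapiro(g)[1] > SHAPIRO_ALPHA for g in (g0, g1)
    )
    if normal:
        p = float(stats.ttest_ind(g0, g1, equal_var=False)[1])
        summary = {str(g): f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"
                   for g, v in zip(groups, (g0, g1))}
        return GroupComparison(variable, "welch", summary, p)
    p = float(stats.mannwhitneyu(g0, g1, alternative="two-sided")[1])
    summary = {
        str(g): f"{v.median():.1f} [{v.quantile(0.25):.1f}-{v.quantile(0.75):.1f}]"
        for g, v in zip(groups, (g0, g1))
    }
    return GroupComparison(variable, "wilcoxon", summary, p)


def impute_gls(values: pd.Series) -> pd.Series:
    """Median-impute sparsely missing strain values (< 5% missing)."""
    values = pd.Series(values, dtype=float)
    frac = values.isna().mean()
    if frac >= 0.05:
        raise DomainError(
            f"{frac:.1%} missing exceeds the 5% median-imputation rule"
        )
    if frac == 0:
        return values.copy()
    return values.fillna(values.median())


def exclude_sparse_binaries(
    cohort: pd.DataFrame, candidates: list[str], outcome: str = "pih"
) -> tuple[list[str], list[dict]]:
    """Drop binaries with < 5 positive observations in either outcome group.

    Returns (retained candidate names, exclusion log).  Non-binary
    candidates pass through untouched.
    """
    y = cohort[outcome]
    retained, log = [], []
    for c in candidates:
        s = cohort[c]
        if not _is_categorical(s) or s.dtype == object:
            retained.append(c)
            continue
        counts = {g: int(s[y == g].sum()) for g in sorted(y.unique())}
        if any(v < 5 for v in counts.values()):
            log.append({"variable": c, "counts": counts})
        else:
            retained.append(c)
    if not retained:
        warnings.warn("all candidates excluded by the sparse-binary rule",
                      stacklevel=2)
    return retained, log


def summary_table(
    cohort: pd.DataFrame, variables: list[str], outcome: str = "pih"
) -> pd.DataFrame:
    """Descriptive comparison CSV rows for a list of variables."""
    rows = []
    for v in variables:
        gc = compare_groups(cohort, v, outcome)
        row = {"variable": v, "test": gc.test, "p": gc.p}
        for g, txt in gc.summary.items():
            row[f"group_{g}"] = txt if isinstance(txt, str) else str(txt)
        rows.append(row)
    return pd.DataFrame(rows)
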