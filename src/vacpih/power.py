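"""Design-stage sample-size computations.

Two calculators cover the study design: precision of a prevalence
estimate (normal-approximation interval half-width), and detection of an
AUC above 0.5 with unequal group sizes using a Hanley-McNeil-type
variance for the Mann-Whitney AUC estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .errors import DomainError

__all__ = ["PowerResult", "n_for_proportion", "inflate_attrition", "n_for_auc"]


def _ceil(x: float) -> int:
    """Ceiling robust to float representation error (100*1.1 -> 110)."""
    return math.ceil(x - 1e-9)


@dataclass(frozen=True)
class PowerResult:
    """Required group sizes for an AUC-based design."""

    n_total: int
    n_pos: int
    n_neg: int
    method: str

    def __post_init__(self):
        assert self.n_pos + self.n_neg == self.n_total


def n_for_proportion(p: float, d: float, conf: float = 0.95) -> int:
    """Sample size to estimate a proportion within half-width ``d``.

    ceil(z^2 * p * (1-p) / d^2) with the two-sided normal quantile at
    ``conf``.
    """
    if not 0 < p < 1:
        raise DomainError(f"p must be in (0,1), got {p!r}")
    if not 0 < d < 1:
        raise DomainError(f"d must be in (0,1), got {d!r}")
    if not 0 < conf < 1:
        raise DomainError(f"conf must be in (0,1), got {conf!r}")
    z = norm.ppf((1 + conf) / 2)
    return _ceil(z**2 * p * (1 - p) / d**2)


def inflate_attrition(n: int, rate: float) -> int:
    """Enrolment target allowing for a dropout fraction: ceil(n*(1+rate))."""
    if not 0 <= rate < 1:
        raise DomainError(f"attrition rate must be in [0,1), got {rate!r}")
    if n < 0:
        raise DomainError(f"n must be >= 0, got {n!r}")
    return _ceil(n * (1 + rate))


def _hanley_mcneil_var(a: float, m: int, n: int) -> float:
    """Variance of the Mann-Whitney AUC under the binormal-free
    Hanley-McNeil approximation (m positives, n negatives)."""
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    return (a * (1 - a) + (m - 1) * (q1 - a**2) + (n - 1) * (q2 - a**2)) / (m * n)


def n_for_auc(
    auc_alt: float,
    alpha: float = 0.05,
    power: float = 0.90,
    kappa: float = 2.0,
    sides: int = 2,
) -> PowerResult:
    """Group sizes to detect AUC = ``auc_alt`` against the 0.5 null.

    Finds the smallest number of positives m (with n = kappa * m
    negatives) such that

        z_{1-alpha/sides} * sqrt(V0) + z_{power} * sqrt(V1) <= auc_alt - 0.5

    where V0 and V1 are Hanley-McNeil variances under the null and the
    alternative.  ``sides=1`` gives the one-sided variant.
    """
    if not 0.5 < auc_alt < 1:
        raise DomainError(f"auc_alt must be in (0.5, 1), got {auc_alt!r}")
    if kappa <= 0:
        raise DomainError(f"kappa must be > 0, got {kappa!r}")
    if sides not in (1, 2):
        raise DomainError("sides must be 1 or 2")
    z_a = norm.ppf(1 - alpha / sides)
    z_b = norm.ppf(power)
    delta = auc_alt - 0.5
    for m in range(2, 100_000):
        n = math.ceil(kappa * m)
        v0 = _hanley_mcneil_var(0.5, m, n)
        v1 = _hanley_mcneil_var(auc_alt, m, n)
        if z_a * math.sqrt(v0) + z_b * math.sqrt(v1) <= delta:
            return PowerResult(
                n_total=m + n, n_pos=m, n_neg=n,
                method=f"hanley-mcneil, {sides}-sided alpha={alpha}, "
                       f"power={power}, kappa={kappa}",
            )
    raise DomainError("no feasible sample size below 100,000 positives")
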