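"""Correlation statistics for evaluating similarity measures.

Semantic-similarity measures are conventionally benchmarked by their
Pearson correlation with an external gold standard (for proteins,
sequence similarity).  Two correlation coefficients estimated on the same
sample are compared through Fisher's variance-stabilising transformation
``z(r) = atanh(r)``: under the null that the population coefficient equals
``rho0``, ``(z(r) − z(rho0))·sqrt(n − 3)`` is approximately standard
normal, giving a one-sample z-test and confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .errors import ParameterError, UndefinedCorrelationError


@dataclass(frozen=True)
class BaselineComparison:
    label: str
    baseline_r: float
    z: float
    p_value: float


@dataclass(frozen=True)
class CorrelationReport:
    """A measured correlation with Fisher-test comparisons to baselines."""

    r: float
    n: int
    comparisons: tuple[BaselineComparison, ...] = ()
    confidence_intervals: dict[float, tuple[float, float]] = field(
        default_factory=dict
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; raises on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("pearson requires two equal-length 1-d sequences")
    if x.size < 2:
        raise UndefinedCorrelationError("need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(_scipy_stats.pearsonr(x, y).statistic)


def _check_fisher_domain(r: float, rho0: float, n: int) -> None:
    if not (abs(r) < 1 and abs(rho0) < 1):
        raise ParameterError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise ParameterError("Fisher transformation requires n >= 4")


def fisher_z_test(r: float, rho0: float, n: int) -> tuple[float, float]:
    """One-sample z-test for a correlation against a fixed null value.

    Returns ``(z, p)`` with ``z = (atanh(r) − atanh(rho0))·sqrt(n − 3)``
    and a two-sided normal p-value.
    """
    _check_fisher_domain(r, rho0, n)
    z = (math.atanh(r) - math.atanh(rho0)) * math.sqrt(n - 3)
    p = 2.0 * float(_scipy_stats.norm.sf(abs(z)))
    return z, p


def fisher_confidence_interval(
    r: float, n: int, level: float
) -> tuple[float, float]:
    """Confidence interval for a correlation via the Fisher transform."""
    _check_fisher_domain(r, 0.0, n)
    if not 0.0 < level < 1.0:
        raise ParameterError("confidence level must lie in (0, 1)")
    zc = float(_scipy_stats.norm.ppf((1.0 + level) / 2.0))
    half = zc / math.sqrt(n - 3)
    centre = math.atanh(r)
    return math.tanh(centre - half), math.tanh(centre + half)


def confidence_level_comparison(
    r1: float, r2: float, n: int, level: float
) -> bool:
    """Do the two correlations' intervals separate at the given level?

    True iff the lower bound of ``r1``'s interval exceeds the upper bound
    of ``r2``'s.
    """
    lo1, _ = fisher_confidence_interval(r1, n, level)
    _, hi2 = fisher_confidence_interval(r2, n, level)
    return lo1 > hi2


def separation_confidence_level(r1: float, r2: float, n: int) -> float:
    """The largest confidence level at which the two intervals separate.

    The intervals ``atanh(r) ± z_c/sqrt(n−3)`` just touch when
    ``z_c = |atanh(r1) − atanh(r2)|·sqrt(n−3)/2``; the corresponding
    two-sided level is returned (0 when r1 == r2).
    """
    _check_fisher_domain(r1, r2, n)
    zc = abs(math.atanh(r1) - math.atanh(r2)) * math.sqrt(n - 3) / 2.0
    return float(2.0 * _scipy_stats.norm.cdf(zc) - 1.0)


def correlation_report(
    x: Sequence[float],
    y: Sequence[float],
    baselines: Sequence[tuple[str, float]] = (),
    levels: Sequence[float] = (0.95, 0.98, 0.99),
) -> CorrelationReport:
    """Correlate two score vectors and test against named baseline r's."""
    r = pearson(x, y)
    n = len(x)
    comparisons = []
    for label, rho0 in baselines:
        z, p = fisher_z_test(r, rho0, n)
        comparisons.append(BaselineComparison(label, rho0, z, p))
    cis = {level: fisher_confidence_interval(r, n, level) for level in levels}
    return CorrelationReport(
        r=r, n=n, comparisons=tuple(comparisons), confidence_intervals=cis
    )
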