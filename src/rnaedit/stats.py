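"""Statistical kernel for RNA-editing discovery.

This module collects the small set of statistics the discovery pipeline is
built from: the exact one-sided binomial upper confidence bound and the
*zero-confidence score* derived from it, exact tests and odds ratios on 2x2
allele-count tables, the strand-bias test, Welch's unequal-variance t test,
and two-group Kaplan-Meier / log-rank survival comparison.

The zero-confidence score quantifies how strongly the DNA reads at a locus
support the *absence* of the alternative (G) allele.  Given ``x`` alternative
reads out of ``n`` total DNA reads, let ``U`` be the exact one-sided
``100*(1-alpha)%`` upper confidence bound on the success probability of a
binomial experiment (the Clopper-Pearson construction, obtained by inverting
the lower tail).  The score is ``-10*log10(U)``: it is 0 when every read is
alternative and grows as deep, alternative-free coverage accumulates.  At
``x = 0`` the bound has the closed form ``U = 1 - alpha**(1/n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "binomial_upper_bound",
    "zero_confidence_score",
    "min_depth_for_score",
    "fisher_exact_2x2",
    "odds_ratio",
    "strand_bias_p",
    "welch_test",
    "km_logrank",
    "bonferroni",
    "WelchResult",
    "LogrankResult",
]

Sidedness = Literal["two_sided", "greater", "less"]
_SIDEDNESS_MAP = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def _validate_binomial(x: int, n: int, alpha: float) -> None:
    if not (isinstance(x, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise TypeError(f"x and n must be integers, got x={x!r}, n={n!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if x < 0 or x > n:
        raise ValueError(f"x must satisfy 0 <= x <= n, got x={x}, n={n}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")


@lru_cache(maxsize=65536)
def binomial_upper_bound(x: int, n: int, alpha: float = 0.05) -> float:
    """Exact one-sided upper confidence bound on a binomial proportion.

    Returns the largest excluded success probability ``U`` such that
    ``P(X <= x | p = U) = alpha``; for ``x = n`` the bound is 1.  This is the
    one-sided Clopper-Pearson bound, equal to the ``1 - alpha`` quantile of
    ``Beta(x + 1, n - x)``.

    Parameters
    ----------
    x : int
        Number of observed successes (alternative-allele reads), ``0 <= x <= n``.
    n : int
        Number of trials (total reads), ``n >= 1``.
    alpha : float
        One minus the confidence level, in (0, 1).
    """
    _validate_binomial(int(x), int(n), float(alpha))
    x, n = int(x), int(n)
    if x == n:
        return 1.0
    if x == 0:
        # closed form: invert alpha = (1 - U)**n
        return 1.0 - float(alpha) ** (1.0 / n)
    return float(_sps.beta.ppf(1.0 - alpha, x + 1, n - x))


def zero_confidence_score(x: int, n: int, alpha: float = 0.05) -> float:
    """Zero-confidence score ``-10*log10(U)`` in deciban-like units.

    ``U`` is :func:`binomial_upper_bound`.  The score is 0 when ``x = n``,
    increases with depth at ``x = 0``, and decreases as alternative reads
    appear.  A high score means high confidence that the locus carries no
    alternative allele in DNA.
    """
    return -10.0 * math.log10(binomial_upper_bound(x, n, alpha))


def min_depth_for_score(threshold: float, alpha: float = 0.05) -> int:
    """Smallest depth ``n`` whose score at ``x = 0`` reaches ``threshold``.

    Solves ``zero_confidence_score(0, n, alpha) >= threshold`` using the
    closed form ``n >= log(alpha) / log(1 - 10**(-threshold/10))``, then
    confirms the boundary by direct evaluation (guards against floating-point
    rounding at exact ties).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    u_target = 10.0 ** (-threshold / 10.0)
    if u_target >= 1.0 - alpha:  # already satisfied at n = 1
        n = 1
    else:
        n = max(1, math.ceil(math.log(alpha) / math.log(1.0 - u_target)))
    while n > 1 and zero_confidence_score(0, n - 1, alpha) >= threshold:
        n -= 1
    while zero_confidence_score(0, n, alpha) < threshold:
        n += 1
    return n


def _validate_table(table: Sequence[Sequence[int]]) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("table cells must be integers")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValueError(f"table cells must be non-negative, got {arr.tolist()}")
    if arr.sum() == 0:
        raise ValueError("all-zero 2x2 table: no reads to test")
    return arr


@lru_cache(maxsize=262144)
def _cached_fisher_p(a: int, b: int, c: int, d: int, alternative: str) -> float:
    return float(_sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def fisher_exact_2x2(table: Sequence[Sequence[int]], sidedness: Sidedness = "two_sided") -> float:
    """Exact (hypergeometric) Fisher test p-value for a 2x2 count table.

    The two-sided p sums the probabilities, over all tables sharing the
    observed margins, of the tables whose point probability does not exceed
    that of the observed table.
    """
    arr = _validate_table(table)
    if sidedness not in _SIDEDNESS_MAP:
        raise ValueError(f"sidedness must be one of {sorted(_SIDEDNESS_MAP)}, got {sidedness!r}")
    a, b, c, d = (int(v) for v in arr.ravel())
    return _cached_fisher_p(a, b, c, d, _SIDEDNESS_MAP[sidedness])


ZeroCellPolicy = Literal["raw", "haldane"]


def odds_ratio(table: Sequence[Sequence[int]], zero_cell_policy: ZeroCellPolicy = "raw") -> float:
    """Cross-product odds ratio ``(a*d) / (b*c)`` of a 2x2 table.

    Under ``raw`` a zero denominator with a positive numerator yields
    ``+inf``, and ``nan`` marks the undefined case where both cross products
    vanish; threshold comparisons such as ``or >= 2.0`` therefore treat an
    infinite ratio as passing.  Under ``haldane`` 0.5 is added to every cell
    first, so the ratio is always finite (useful for report tables).
    """
    arr = _validate_table(table).astype(float)
    if zero_cell_policy == "haldane":
        arr = arr + 0.5
    elif zero_cell_policy != "raw":
        raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    a, b, c, d = arr.ravel()
    num, den = a * d, b * c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def strand_bias_p(ref_plus: int, ref_minus: int, alt_plus: int, alt_minus: int) -> float:
    """Two-sided Fisher p for the strand x allele table.

    Rows are forward/reverse strand counts of the reference and alternative
    alleles; a locus passes the bias filter when the p-value is not small
    (artifactual calls place alternative reads on one strand only).
    """
    if alt_plus == 0 and alt_minus == 0:
        # no alternative reads: bias over alleles is undefined, trivially unbiased
        if ref_plus == 0 and ref_minus == 0:
            raise ValueError("all-zero strand table")
        return 1.0
    return fisher_exact_2x2([[ref_plus, alt_plus], [ref_minus, alt_minus]])


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    p_value: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.p_value)


def welch_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t test (two-sided).

    Each group needs at least two values and the pooled data nonzero
    variance; otherwise the test is undefined and ``nan`` is returned as a
    marker (callers treat undefined as "not significant").
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return WelchResult(math.nan, math.nan)
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if float(a.mean()) == float(b.mean()):
            # identical constants: no evidence of difference
            return WelchResult(0.0, 1.0)
        return WelchResult(math.nan, math.nan)
    stat, p = _sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(stat), float(p))


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    curves: dict = field(repr=False, default_factory=dict)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.p_value)


def km_logrank(
    time: Sequence[float],
    event: Sequence[bool],
    group: Sequence,
    compute_curves: bool = True,
) -> LogrankResult:
    """Kaplan-Meier curves and two-group log-rank test.

    Parameters are parallel arrays of follow-up time (days), event indicator
    (True = death observed, False = censored) and a binary group label
    (e.g. edited / non-edited).  Ties are handled by the standard
    hypergeometric variance at each distinct event time.  Returns per-group
    product-limit curves (as DataFrames with columns ``time``, ``survival``,
    ``n_at_risk``) plus the 1-df chi-square statistic and p-value; if no
    events occurred at all the test is undefined and ``nan`` is returned.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    g = np.asarray(group)
    if not (t.shape == e.shape == g.shape):
        raise ValueError("time, event and group must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival times")
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(labels)}")
    curves = {}
    for lab in labels:
        mask = g == lab
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} has no records")
        if not compute_curves:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                "n_at_risk": kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float),
            }
        )
    if not e.any():
        return LogrankResult(math.nan, math.nan, curves)
    m0 = g == labels[0]
    res = logrank_test(t[m0], t[~m0], event_observed_A=e[m0], event_observed_B=e[~m0])
    return LogrankResult(float(res.test_statistic), float(res.p_value), curves)


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value, ``min(1, p * n_tests)``."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    return min(1.0, p * n_tests)
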