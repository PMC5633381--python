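"""Fluctuation-assay rate estimation by the method of the median.

Given the median number ``r_med`` of resistant colonies over parallel
cultures, the expected number of founding events per culture ``m`` solves the
Lea–Coulson median equation

    r_med / m  -  ln m  =  1.24,

and the rate per cell division is ``mu = m / (N_final - N0)`` (one division
per new daughter cell, so a culture grown from ``N0`` to ``N_final`` cells
underwent ``N_final - N0`` divisions).  Rates are conventionally reported per
10^7 cell divisions.

Two labelled estimator variants are provided:

* ``per-culture`` (default): the median equation is applied to each
  culture's count, yielding a per-culture rate (0 for cultures with no
  resistant colonies, since ``m -> 0`` as ``r -> 0``); the reported rate is
  the median of these, with a distribution-free order-statistic confidence
  interval on that median.
* ``pooled-median``: the textbook form — the equation is applied once to the
  median count across cultures; the CI is obtained by transforming the
  order-statistic CI of the counts (the count-to-rate map is monotone).

When every culture shares the same final population the two medians
coincide; they differ on real data with per-culture population sizes.  When
the median count is zero the p0 method (``m = -ln(fraction of cultures with
r = 0)``) is used instead and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .simulate import CultureResult

__all__ = [
    "RateEstimate",
    "MedianCI",
    "lea_coulson_m",
    "p0_method_m",
    "culture_rate",
    "median_with_ci",
    "class_rate_table",
    "subtract_rates",
    "TOTAL_LABEL",
    "NON_CL_LABEL",
]

_LEA_COULSON_CONST = 1.24
TOTAL_LABEL = "TOTAL"
NON_CL_LABEL = "NON_CL"


class ZeroMedianError(ValueError):
    """Median count is zero: the median equation has no positive solution."""


def lea_coulson_m(r_med: float) -> float:
    """Solve the Lea–Coulson median equation for the expected events ``m``.

    Solves ``r_med = m (ln m + 1.24)`` to relative tolerance 1e-9; the
    solution is unique and monotone increasing in ``r_med`` on the branch
    ``m > exp(-1.24)``.  ``r_med = 0`` signals that the p0 method must be
    used instead.
    """
    if r_med < 0:
        raise ValueError(f"median count must be >= 0, got {r_med}")
    if r_med == 0:
        raise ZeroMedianError(
            "median resistant count is 0; use p0_method_m on the zero fraction"
        )

    def f(m: float) -> float:
        return m * (math.log(m) + _LEA_COULSON_CONST) - r_med

    lo = math.exp(-_LEA_COULSON_CONST)  # where m(ln m + 1.24) = 0
    hi = max(1.0, float(r_med))
    while f(hi) < 0:  # safety; cannot trigger for r >= 0.787 or hi = 1
        hi *= 2
    return float(optimize.brentq(f, lo, hi, xtol=1e-300, rtol=1e-12))


def p0_method_m(fraction_zero: float) -> float:
    """Events per culture from the fraction of cultures with no resistant cells."""
    if not (0.0 < fraction_zero <= 1.0):
        raise ValueError(
            "p0 method needs a strictly positive fraction of zero cultures"
        )
    return -math.log(fraction_zero)


def culture_rate(r: float, n_final: float, n0: float = 1.0) -> float:
    """Per-division event rate for one culture via the median equation.

    ``r = 0`` maps to rate 0 (the ``m -> 0`` limit), so zero cultures sit at
    the bottom of the order statistics rather than being discarded.
    """
    if n_final <= n0 or n0 < 1:
        raise ValueError("need n_final > n0 >= 1")
    if r < 0:
        raise ValueError("resistant count must be >= 0")
    if r > n_final:
        raise ValueError("resistant count exceeds final population")
    if r == 0:
        return 0.0
    return lea_coulson_m(r) / (n_final - n0)


@dataclass(frozen=True)
class MedianCI:
    """Median with a distribution-free order-statistic confidence interval."""

    median: float
    lower: Optional[float]
    upper: Optional[float]
    achieved_level: Optional[float]
    requested_level: float
    n: int
    lower_rank: Optional[int]  # 1-based
    upper_rank: Optional[int]
    level_attained: bool


def median_with_ci(values: Sequence[float], level: float = 0.95) -> MedianCI:
    """Median and exact binomial order-statistic CI (sign-test inversion).

    The interval is ``[x_(l), x_(n+1-l)]`` with ``l`` the largest rank whose
    two-tailed Binomial(n, 1/2) probability outside the interval is at most
    ``1 - level``; the achieved coverage ``1 - 2 P(X <= l-1)`` is reported.
    For ``n`` too small to attain the requested level even at the extreme
    ranks, the full range is returned and flagged.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must be in (0, 1)")
    ordered = np.sort(np.asarray(values, dtype=float))
    n = ordered.size
    if n < 1:
        raise ValueError("need at least one value")
    median = float(np.median(ordered))
    if n < 2:
        return MedianCI(median, None, None, None, level, n, None, None, False)

    # largest l with 2 * P(Bin(n, 1/2) <= l - 1) <= 1 - level
    best_l = 0
    for l in range(1, n // 2 + 1):
        if 2.0 * stats.binom.cdf(l - 1, n, 0.5) <= 1.0 - level:
            best_l = l
    if best_l == 0:
        achieved = 1.0 - 2.0 * stats.binom.cdf(0, n, 0.5)
        return MedianCI(
            median, float(ordered[0]), float(ordered[-1]), float(achieved),
            level, n, 1, n, level_attained=False,
        )
    achieved = 1.0 - 2.0 * stats.binom.cdf(best_l - 1, n, 0.5)
    return MedianCI(
        median,
        float(ordered[best_l - 1]),
        float(ordered[n - best_l]),
        float(achieved),
        level,
        n,
        best_l,
        n + 1 - best_l,
        level_attained=True,
    )


@dataclass(frozen=True)
class RateEstimate:
    """Median LOH rate per cell division for one event class."""

    class_label: str
    median_rate: float
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    achieved_level: Optional[float]
    requested_level: float
    n_cultures: int
    per_culture_rates: tuple[float, ...] = ()
    method: str = "per-culture"  # per-culture | pooled-median | p0 | subtraction
    flags: tuple[str, ...] = ()
    pooled_median_rate: Optional[float] = None

    @property
    def per_1e7(self) -> float:
        return self.median_rate * 1e7

    def __post_init__(self) -> None:
        if self.ci_lower is not None and self.ci_upper is not None:
            if not (self.ci_lower <= self.ci_upper):
                raise ValueError("CI lower bound exceeds upper bound")


def _estimate_for_counts(
    label: str,
    counts: Sequence[float],
    divisions: Sequence[float],
    level: float,
    estimator: str,
) -> RateEstimate:
    counts = np.asarray(counts, dtype=float)
    divisions = np.asarray(divisions, dtype=float)
    n = counts.size
    median_divisions = float(np.median(divisions))
    flags: list[str] = []

    per_culture = tuple(
        culture_rate(r, d + 1.0, 1.0) for r, d in zip(counts, divisions)
    )  # divisions d = n_final - n0 directly
    median_r = float(np.median(counts))

    if median_r == 0:
        frac_zero = float(np.mean(counts == 0))
        if np.all(counts == 0):
            # class unobserved: rate 0 with a p0-style upper bound at the
            # resolution limit of n cultures
            upper = -math.log((n - 0.5) / n) / median_divisions
            return RateEstimate(
                label, 0.0, 0.0, upper, None, level, n, per_culture,
                method="p0", flags=("unobserved", "upper-bound-only"),
            )
        m = p0_method_m(frac_zero)
        return RateEstimate(
            label, m / median_divisions, None, None, None, level, n,
            per_culture, method="p0", flags=("zero-median",),
        )

    if estimator == "per-culture":
        ci = median_with_ci(per_culture, level)
        median_rate = ci.median
    elif estimator == "pooled-median":
        count_ci = median_with_ci(counts, level)
        median_rate = lea_coulson_m(median_r) / median_divisions
        lower = (
            culture_rate(count_ci.lower, median_divisions + 1.0)
            if count_ci.lower is not None else None
        )
        upper = (
            culture_rate(count_ci.upper, median_divisions + 1.0)
            if count_ci.upper is not None else None
        )
        ci = MedianCI(
            median_rate, lower, upper, count_ci.achieved_level, level, n,
            count_ci.lower_rank, count_ci.upper_rank, count_ci.level_attained,
        )
    else:
        raise ValueError(f"unknown estimator variant {estimator!r}")

    if not ci.level_attained:
        flags.append("requested-level-unattainable")
    pooled = lea_coulson_m(median_r) / median_divisions
    return RateEstimate(
        label, median_rate, ci.lower, ci.upper, ci.achieved_level, level, n,
        per_culture, method=estimator, flags=tuple(flags),
        pooled_median_rate=pooled,
    )


def class_rate_table(
    cultures: Sequence[CultureResult],
    level: float = 0.95,
    estimator: str = "per-culture",
    include_total: bool = True,
    include_non_cl: bool = True,
) -> dict[str, RateEstimate]:
    """Per-class rate estimates from classified fluctuation cultures.

    Observed selective-plate counts are corrected for plating dilution
    (divided by ``dilution × plating_efficiency``) before estimation.  The
    ``TOTAL`` row pools all classes; ``NON_CL`` is the derived
    rate ``TOTAL - CL`` (no CI).
    """
    if len(cultures) < 2:
        raise ValueError("need at least 2 cultures")
    labels: list[str] = []
    for culture in cultures:
        for label in culture.resistant_by_class:
            if label not in labels:
                labels.append(label)
    divisions = [float(c.divisions) for c in cultures]

    def corrected(culture: CultureResult, label: str) -> float:
        keep = culture.dilution * culture.plating_efficiency
        return culture.resistant_by_class.get(label, 0) / keep

    table: dict[str, RateEstimate] = {}
    for label in labels:
        counts = [corrected(c, label) for c in cultures]
        table[label] = _estimate_for_counts(label, counts, divisions, level, estimator)
    if include_total:
        totals = [
            sum(corrected(c, label) for label in labels) for c in cultures
        ]
        table[TOTAL_LABEL] = _estimate_for_counts(
            TOTAL_LABEL, totals, divisions, level, estimator
        )
        from .markers import LOHClass

        cl_label = LOHClass.CHROMOSOME_LOSS.value
        if include_non_cl and cl_label in table:
            table[NON_CL_LABEL] = subtract_rates(table[TOTAL_LABEL], table[cl_label])
    return table


def subtract_rates(total: RateEstimate, part: RateEstimate) -> RateEstimate:
    """Derived rate ``total - part`` (e.g. non-CL = total LOH minus CL).

    Clamped at zero; confidence limits are not propagated through the
    subtraction and are reported as unavailable.
    """
    if total.n_cultures != part.n_cultures:
        raise ValueError("estimates come from different assays (culture counts differ)")
    diff = total.median_rate - part.median_rate
    flags = ("part-exceeds-total",) if diff < 0 else ()
    if diff < 0:
        warnings.warn(
            f"subtracted rate {part.class_label} exceeds {total.class_label}; "
            "clamping to 0",
            stacklevel=2,
        )
    return RateEstimate(
        class_label=f"{total.class_label}-minus-{part.class_label}"
        if total.class_label != TOTAL_LABEL
        else NON_CL_LABEL,
        median_rate=max(0.0, diff),
        ci_lower=None,
        ci_upper=None,
        achieved_level=None,
        requested_level=total.requested_level,
        n_cultures=total.n_cultures,
        method="subtraction",
        flags=("no-ci",) + flags,
    )
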