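"""Inferential toolkit for LOH analyses.

Exact and asymptotic contingency tests with multiple-testing correction, the
independent-events product null with a binomial tail test, rate comparisons
(Welch t, Mann–Whitney), and the pulsed-field-gel chromosome II fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_2x2",
    "two_proportion_chisq",
    "holm_bonferroni",
    "independence_expected_rate",
    "binomial_independence_test",
    "welch_t_test",
    "mann_whitney",
    "pfge_chr2_fraction",
    "round_to_sig",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 count table with optional row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table has no observations")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    p_value: float
    statistic: Optional[float] = None
    p_adjusted: Optional[float] = None
    tails: str = "two-sided"
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p below raw p")

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_raw": self.p_value,
            "p_adjusted": self.p_adjusted,
            "tails": self.tails,
            "n": self.n,
        }


def fisher_exact_2x2(
    table: ContingencyTable2x2, tails: str = "two-sided"
) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p-value sums hypergeometric probabilities of all tables
    with the observed margins whose point probability does not exceed the
    observed table's (point-probability ordering).
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("Fisher test undefined for a table with an empty margin")
    alternative = {"two-sided": "two-sided", "less": "less", "greater": "greater"}[tails]
    odds, p = sps.fisher_exact(arr, alternative=alternative)
    return TestResult(
        method="fisher-exact",
        statistic=float(odds) if math.isfinite(odds) else None,
        p_value=float(min(1.0, p)),
        tails=tails,
        n=int(arr.sum()),
    )


def two_proportion_chisq(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """1-df Pearson chi-square comparing two proportions, no continuity correction.

    Warns (recommending the exact test) when any expected cell is below 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must lie within sample sizes")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 1).any():
        warnings.warn(
            "expected cell count below 1; prefer fisher_exact_2x2", stacklevel=2
        )
    if (expected == 0).any():
        raise ValueError("degenerate table: zero expected cell")
    statistic = float(((table - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(statistic, df=1))
    return TestResult(
        method="two-proportion-chisq",
        statistic=statistic,
        p_value=p,
        n=int(n1 + n2),
    )


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p_values = list(p_values)
    if not p_values:
        return []
    if any(not (0.0 <= p <= 1.0) for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p_values, method="holm")
    return [float(p) for p in adjusted]


def independence_expected_rate(rate_a: float, rate_b: float) -> float:
    """Expected joint rate of two independent per-division events: the product."""
    if rate_a < 0 or rate_b < 0:
        raise ValueError("rates must be >= 0")
    return rate_a * rate_b


def round_to_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (used for report presentation)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + sig - 1)


_BINOM_EXACT_LIMIT = 10_000_000


def binomial_independence_test(
    k_observed: int, n_divisions: int, p0: float
) -> TestResult:
    """Upper-tail binomial test of observed events against an expected rate.

    p = P(X >= k | X ~ Binomial(n, p0)), computed exactly for
    n <= 10^7 and by the Poisson limit (lambda = n p0) above that; in the
    validated regime (n p0 <= 1e3 at the switch point) the approximation
    agrees with exact summation to relative error < 1e-3.
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must lie in [0, 1]")
    if not (0 <= k_observed <= n_divisions):
        raise ValueError("k must lie in [0, n]")
    if k_observed == 0:
        p = 1.0
    elif n_divisions <= _BINOM_EXACT_LIMIT:
        p = float(sps.binom.sf(k_observed - 1, n_divisions, p0))
    else:
        p = float(sps.poisson.sf(k_observed - 1, n_divisions * p0))
    return TestResult(
        method="binomial-upper-tail",
        statistic=float(k_observed),
        p_value=min(1.0, p),
        tails="greater",
        n=n_divisions,
    )


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Welch (unequal-variance) t-test."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if float(a.mean()) == float(b.mean()):
            return TestResult(
                method="welch-t", statistic=0.0, p_value=1.0, n=int(a.size + b.size)
            )
        raise ValueError("both samples have zero variance; t statistic undefined")
    statistic, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        method="welch-t",
        statistic=float(statistic),
        p_value=float(p),
        n=int(a.size + b.size),
    )


_MW_EXACT_LIMIT = 20  # combined sample size for exact enumeration


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney rank-sum test.

    Exact null enumeration for combined n <= 20 without ties; the
    tie-corrected normal approximation otherwise.  Fully tied data carry no
    ordering information and return p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return TestResult(
            method="mann-whitney", statistic=float(a.size * b.size / 2.0),
            p_value=1.0, n=int(pooled.size),
        )
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= _MW_EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    statistic, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        method="mann-whitney",
        statistic=float(statistic),
        p_value=float(min(1.0, p)),
        n=int(pooled.size),
    )


def pfge_chr2_fraction(vol_ii: float, vol_xiv: float, vol_x: float) -> float:
    """Chromosome II band volume as a fraction of chromosomes II + XIV + X.

    The normalisation corrects lane-to-lane loading differences; monosomy of
    chromosome II shows up as a drop from the euploid fraction.
    """
    volumes = (vol_ii, vol_xiv, vol_x)
    if any(v < 0 for v in volumes):
        raise ValueError("band volumes must be >= 0")
    total = sum(volumes)
    if total == 0:
        raise ValueError("all band volumes are zero; fraction undefined")
    return vol_ii / total
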