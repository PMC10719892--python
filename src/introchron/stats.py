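"""Shared statistical kernel.

Every association, rank, regression and permutation statistic used by the
pipeline routes through this module so that conventions (odds-ratio
definition, two-sidedness, empirical-p plus-one rule, Bonferroni
formatting) are fixed in exactly one place.

Conventions
-----------
* Odds ratios are the sample cross-product ratio ``(a*d)/(b*c)``, not the
  conditional maximum-likelihood estimate.
* Empirical permutation p-values use the plus-one rule
  ``(1 + #{null >= observed}) / (n_iter + 1)`` and therefore can never be 0.
* Extremely small p-values are additionally reported in log10 space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "PermutationResult",
    "ClineResult",
    "MannWhitneyResult",
    "fisher_exact",
    "mann_whitney",
    "linear_fit",
    "permutation_enrichment",
    "bonferroni_threshold",
    "round_sig",
]

#: above this table total the exact hypergeometric p is replaced by a
#: chi-square approximation (method recorded in the result)
EXACT_TOTAL_LIMIT = 100_000


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; ``a`` is the both-conditions cell.

    Layout::

                     in-region   not-in-region
        condition        a             b
        background       c             d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("contingency table must have a positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_margin(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class EnrichmentResult:
    """Odds ratio + p-value for a 2x2 association, with bookkeeping flags."""

    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    method: str
    or_defined: bool = True
    log10_p: float | None = None
    significance_tier: str = "ns"  # {"ns", "nominal", "corrected"}
    label: str | None = None
    flags: tuple[str, ...] = ()

    def tier_against(self, alpha: float, corrected_threshold: float) -> str:
        if self.p_value <= corrected_threshold:
            return "corrected"
        if self.p_value <= alpha:
            return "nominal"
        return "ns"


@dataclass
class PermutationResult:
    """Observed statistic against a permutation null.

    ``enrichment`` is observed / mean(null); ``empirical_p`` uses the
    plus-one rule and lies in (0, 1].
    """

    observed: float
    null_mean: float
    enrichment: float
    empirical_p: float
    n_iter: int
    seed: int
    enrichment_defined: bool = True
    flags: tuple[str, ...] = ()


@dataclass
class ClineResult:
    """OLS slope/intercept plus the signed Pearson correlation."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    degenerate: bool = False


@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    n_x: int
    n_y: int
    degenerate: bool = False


def _cross_product_or(t: ContingencyTable2x2) -> tuple[float, bool]:
    if t.b * t.c > 0:
        return (t.a * t.d) / (t.b * t.c), True
    if t.a * t.d > 0:
        return math.inf, False
    return 0.0, False


def fisher_exact(table: ContingencyTable2x2) -> EnrichmentResult:
    """Two-sided test of association for a 2x2 table.

    Exact hypergeometric p for totals up to ``EXACT_TOTAL_LIMIT``; beyond
    that a chi-square approximation is used and recorded in ``method``.
    The odds ratio is always the sample cross-product ratio.
    """
    odds_ratio, or_defined = _cross_product_or(table)
    flags: list[str] = []
    if table.has_zero_margin:
        return EnrichmentResult(
            table=table,
            odds_ratio=0.0 if table.a * table.d == 0 else math.inf,
            p_value=1.0,
            method="degenerate-zero-margin",
            or_defined=False,
            log10_p=0.0,
            flags=("zero_margin",),
        )
    if not or_defined:
        flags.append("or_undefined")
    if table.total <= EXACT_TOTAL_LIMIT:
        _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
        method = "fisher-exact"
        log10_p = math.log10(p) if p > 0 else -math.inf
    else:
        chi2, p, _, _ = sps.chi2_contingency(table.as_array(), correction=False)
        method = "chi2-approx"
        if p > 0:
            log10_p = math.log10(p)
        else:
            # survival-function underflow: recover log10 p from the chi2 tail
            log10_p = (sps.chi2.logsf(chi2, df=1)) / math.log(10)
        p = float(p)
    return EnrichmentResult(
        table=table,
        odds_ratio=odds_ratio,
        p_value=float(p),
        method=method,
        or_defined=or_defined,
        log10_p=float(log10_p),
        flags=tuple(flags),
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with tie correction.

    Exact null enumeration for small tie-free samples, normal
    approximation otherwise (scipy's ``method="auto"`` policy).
    All-tied degenerate input returns p = 1 with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(
            u_statistic=x.size * y.size / 2.0,
            p_value=1.0,
            n_x=x.size,
            n_y=y.size,
            degenerate=True,
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_x=x.size,
        n_y=y.size,
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> ClineResult:
    """Ordinary least squares of y on x with the signed Pearson r.

    The p-value is the two-sided t-test on the slope. Constant x or y is
    degenerate: r is reported as NaN with the flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("x must not be constant")
    if np.all(y == y[0]):
        return ClineResult(
            slope=0.0, intercept=float(y[0]), pearson_r=math.nan, p_value=1.0, degenerate=True
        )
    res = sps.linregress(x, y)
    return ClineResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
    )


def permutation_enrichment(
    observed_stat: float,
    null_sampler: Callable[[np.random.Generator], float],
    n_iter: int,
    seed: int,
) -> PermutationResult:
    """Generic permutation framework.

    ``null_sampler`` draws one null statistic per call from the provided
    generator; results are reproducible given ``seed``. ``empirical_p``
    uses the plus-one rule, so it is never exactly 0.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter, dtype=float)
    for i in range(n_iter):
        null[i] = null_sampler(rng)
    null_mean = float(null.mean())
    n_ge = int(np.count_nonzero(null >= observed_stat))
    empirical_p = (1 + n_ge) / (n_iter + 1)
    if null_mean == 0:
        return PermutationResult(
            observed=float(observed_stat),
            null_mean=0.0,
            enrichment=math.nan,
            empirical_p=empirical_p,
            n_iter=n_iter,
            seed=seed,
            enrichment_defined=False,
            flags=("null_mean_zero",),
        )
    return PermutationResult(
        observed=float(observed_stat),
        null_mean=null_mean,
        enrichment=float(observed_stat) / null_mean,
        empirical_p=empirical_p,
        n_iter=n_iter,
        seed=seed,
    )


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class BonferroniThreshold:
    alpha: float
    m: int
    value: float
    value_3sig: float


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> BonferroniThreshold:
    """Family-wise corrected per-test threshold alpha/m.

    Returned both at full precision and rounded to 3 significant figures
    (the form used when quoting the threshold, e.g. 0.05/49 -> 0.00102).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    value = alpha / m
    return BonferroniThreshold(alpha=alpha, m=m, value=value, value_3sig=round_sig(value, 3))
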