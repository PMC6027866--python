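"""Base-substitution rate estimation with exact Poisson confidence intervals.

Mutations accumulated by an MA line are modelled as a Poisson process over
*exposure* — callable nucleotide sites times cell divisions, summed over
lines (site-divisions). The point rate is count/exposure; interval bounds use
the exact (Garwood) construction from chi-square quantiles rather than a
normal or score approximation, which matters at the counts of a few dozen
typical for these experiments. Pooling across lines is always
counts-over-pooled-exposure, never a mean of per-line rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from scipy import stats

from .spectra import AT_GAINING, GC_GAINING, MutationClass, SpectrumCounts

__all__ = [
    "LineMeta",
    "RateEstimate",
    "ConditionalRates",
    "cell_divisions",
    "poisson_ci",
    "exposure",
    "estimate_rate",
    "conditional_rates",
    "per_class_rates",
    "compare_rates",
]


def cell_divisions(
    n_transfers: int, divisions_per_cycle: float, *, nearest: Optional[int] = None
) -> float:
    """Total cell divisions a line experienced: transfers x divisions/cycle.

    ``nearest`` rounds to the closest multiple (e.g. ``nearest=10`` turns
    148 transfers x 6.6 divisions/cycle = 976.8 into the reported 980).
    """
    if n_transfers <= 0 or divisions_per_cycle <= 0:
        raise ValueError("transfers and divisions per cycle must be positive")
    total = n_transfers * divisions_per_cycle
    if nearest is not None:
        if nearest <= 0:
            raise ValueError("nearest must be a positive integer")
        return round(total / nearest) * nearest
    return total


@dataclass(frozen=True)
class LineMeta:
    """Exposure bookkeeping for one MA line.

    ``callable_sites_AT`` / ``callable_sites_GC`` are the numbers of callable
    positions whose reference base is A/T respectively G/C; their sum is the
    denominator of the overall rate, the split feeds the conditional rates
    u (toward G/C) and v (toward A/T).
    """

    line_id: str
    n_transfers: int
    divisions_per_cycle: float
    callable_sites_AT: int
    callable_sites_GC: int

    def __post_init__(self) -> None:
        if self.callable_sites_AT < 0 or self.callable_sites_GC < 0:
            raise ValueError(f"{self.line_id}: negative callable-site count")
        if self.callable_sites_AT + self.callable_sites_GC == 0:
            raise ValueError(f"{self.line_id}: no callable sites")
        if self.n_transfers <= 0 or self.divisions_per_cycle <= 0:
            raise ValueError(f"{self.line_id}: non-positive exposure terms")

    @property
    def total_divisions(self) -> float:
        return self.n_transfers * self.divisions_per_cycle

    @property
    def callable_sites(self) -> int:
        return self.callable_sites_AT + self.callable_sites_GC


def poisson_ci(n: int, confidence: float = 0.95) -> Tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval for a count.

    low = 0 for n = 0, else chi2.ppf(alpha/2, 2n)/2;
    high = chi2.ppf(1 - alpha/2, 2(n+1))/2 — equivalently gamma quantiles.
    Returned in count units; divide by exposure for a rate interval.
    """
    if n < 0 or int(n) != n:
        raise ValueError(f"count must be a nonnegative integer, got {n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    alpha = 1.0 - confidence
    low = 0.0 if n == 0 else 0.5 * stats.chi2.ppf(alpha / 2.0, 2 * n)
    high = 0.5 * stats.chi2.ppf(1.0 - alpha / 2.0, 2 * (n + 1))
    return float(low), float(high)


def exposure(lines: Iterable[LineMeta], which_sites: str = "all") -> float:
    """Pooled exposure in site-divisions over lines.

    ``which_sites`` selects the callable-site class: ``"all"``, ``"AT"`` or
    ``"GC"``.
    """
    if which_sites not in ("all", "AT", "GC"):
        raise ValueError(f"which_sites must be 'all', 'AT' or 'GC', got {which_sites!r}")
    total = 0.0
    for line in lines:
        if which_sites == "all":
            sites = line.callable_sites
        elif which_sites == "AT":
            sites = line.callable_sites_AT
        else:
            sites = line.callable_sites_GC
        total += sites * line.total_divisions
    return total


@dataclass(frozen=True)
class RateEstimate:
    """A Poisson rate: count over exposure, with an exact interval."""

    n_mutations: int
    exposure: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if self.n_mutations < 0:
            raise ValueError("mutation count must be nonnegative")

    @property
    def rate(self) -> float:
        return self.n_mutations / self.exposure

    @property
    def ci(self) -> Tuple[float, float]:
        low, high = poisson_ci(self.n_mutations, self.confidence)
        return low / self.exposure, high / self.exposure

    @property
    def ci_low(self) -> float:
        return self.ci[0]

    @property
    def ci_high(self) -> float:
        return self.ci[1]


def estimate_rate(
    n: int,
    lines: Sequence[LineMeta],
    which_sites: str = "all",
    confidence: float = 0.95,
) -> RateEstimate:
    """Pooled rate per site per cell division for ``n`` observed mutations.

    Exposure is the sum over lines of the selected callable sites times total
    divisions; the estimate is invariant to how exposure is partitioned among
    lines.
    """
    pooled = exposure(lines, which_sites)
    if pooled <= 0:
        raise ValueError(f"zero {which_sites} exposure across {len(lines)} lines")
    return RateEstimate(n_mutations=n, exposure=pooled, confidence=confidence)


@dataclass(frozen=True)
class ConditionalRates:
    """Directional mutation rates and bias.

    u: rate toward G/C (A:T->G:C and A:T->C:G events over A/T-site exposure);
    v: rate toward A/T (G:C->A:T and G:C->T:A events over G/C-site exposure);
    m = u/v is the G/C-direction mutation bias (``None`` when v = 0). The
    pair-conserving classes A:T->T:A and G:C->C:G enter neither rate.
    """

    u: float
    v: float

    def __post_init__(self) -> None:
        if self.u < 0 or self.v < 0:
            raise ValueError("conditional rates must be nonnegative")

    @property
    def m(self) -> Optional[float]:
        if self.v == 0:
            return None
        return self.u / self.v


def conditional_rates(
    spectrum: SpectrumCounts, lines: Sequence[LineMeta]
) -> ConditionalRates:
    """Compute u, v (and through them the bias m) from a folded spectrum."""
    e_at = exposure(lines, "AT")
    e_gc = exposure(lines, "GC")
    if e_at <= 0 or e_gc <= 0:
        raise ValueError("both A/T and G/C exposures must be positive")
    u = sum(spectrum[cls] for cls in GC_GAINING) / e_at
    v = sum(spectrum[cls] for cls in AT_GAINING) / e_gc
    return ConditionalRates(u=u, v=v)


def per_class_rates(
    spectrum: SpectrumCounts,
    lines: Sequence[LineMeta],
    confidence: float = 0.95,
) -> Dict[MutationClass, RateEstimate]:
    """Conditional rate per class: count over its source-pair exposure."""
    pooled = {"AT": exposure(lines, "AT"), "GC": exposure(lines, "GC")}
    for pair, value in pooled.items():
        if value <= 0:
            raise ValueError(f"zero exposure for {pair} source sites")
    return {
        cls: RateEstimate(
            n_mutations=spectrum[cls],
            exposure=pooled[cls.source_pair],
            confidence=confidence,
        )
        for cls in MutationClass
    }


def compare_rates(n1: int, e1: float, n2: int, e2: float) -> float:
    """Exact conditional test that two Poisson rates are equal.

    Given the total N = n1 + n2, under the null n1 ~ Binomial(N, e1/(e1+e2)).
    The two-sided p-value doubles the smaller tail and is capped at 1.
    """
    if e1 <= 0 or e2 <= 0:
        raise ValueError("exposures must be positive")
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be nonnegative")
    total = n1 + n2
    if total < 1:
        raise ValueError("need at least one event to compare rates")
    p_null = e1 / (e1 + e2)
    lower = stats.binom.cdf(n1, total, p_null)
    upper = stats.binom.sf(n1 - 1, total, p_null)
    return float(min(1.0, 2.0 * min(lower, upper)))
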