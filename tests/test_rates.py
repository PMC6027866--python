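"""Exact Poisson intervals, pooled rate estimation, and the conditional test."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq

from mamut.rates import (
    ConditionalRates,
    LineMeta,
    RateEstimate,
    cell_divisions,
    compare_rates,
    conditional_rates,
    estimate_rate,
    exposure,
    per_class_rates,
    poisson_ci,
)
from mamut.spectra import MutationClass, SpectrumCounts


def poisson_ci_by_cdf_inversion(n, confidence=0.95):
    """Independent oracle: numeric inversion of the Poisson CDF."""
    alpha = 1.0 - confidence
    low = 0.0
    if n > 0:
        low = brentq(lambda lam: stats.poisson.sf(n - 1, lam) - alpha / 2, 1e-12, 10 * n + 50)
    high = brentq(lambda lam: stats.poisson.cdf(n, lam) - alpha / 2, 1e-12, 10 * n + 200)
    return low, high


def test_poisson_ci_frozen_values():
    assert poisson_ci(0) == pytest.approx((0.0, 3.6889), abs=1e-4)
    assert poisson_ci(29) == pytest.approx((19.4218, 41.6488), abs=1e-4)
    assert poisson_ci(24) == pytest.approx((15.3773, 35.7101), abs=1e-4)


@pytest.mark.parametrize("n", [0, 1, 2, 5, 13, 29, 50, 100])
def test_poisson_ci_matches_numeric_inversion(n):
    low, high = poisson_ci(n)
    olow, ohigh = poisson_ci_by_cdf_inversion(n)
    assert low == pytest.approx(olow, rel=1e-6, abs=1e-9)
    assert high == pytest.approx(ohigh, rel=1e-6, abs=1e-9)


def test_poisson_ci_rejects_bad_inputs():
    with pytest.raises(ValueError):
        poisson_ci(-1)
    with pytest.raises(ValueError):
        poisson_ci(3, confidence=1.0)


def _one_line(sites_at, sites_gc, divisions=100.0):
    return LineMeta("L1", 1, divisions, sites_at, sites_gc)


def test_estimate_rate_matches_printed_table_values():
    """Counts of 29 and 24 over supplement-scale exposures give the published rates."""
    lines = [_one_line(1_188_500_000, 0, divisions=1000.0)]  # 1.1885e12 site-divisions
    est = estimate_rate(29, lines)
    assert est.rate * 1e11 == pytest.approx(2.44, abs=0.005)
    lines = [_one_line(991_700_000, 0, divisions=1000.0)]  # 9.917e11
    est = estimate_rate(24, lines)
    assert est.rate * 1e11 == pytest.approx(2.42, abs=0.005)


def test_zero_count_rate_and_interval():
    lines = [_one_line(1000, 0, divisions=10.0)]
    est = estimate_rate(0, lines)
    assert est.rate == 0.0
    assert est.ci_low == 0.0
    assert est.ci_high == pytest.approx(3.6889 / 10_000, rel=1e-4)


@given(
    sites=st.lists(st.integers(min_value=1, max_value=10**7), min_size=1, max_size=8),
    divisions=st.floats(min_value=1.0, max_value=2000.0),
    n=st.integers(min_value=0, max_value=100),
)
def test_rate_invariant_to_exposure_partitioning(sites, divisions, n):
    """Pooling is counts-over-pooled-exposure: splitting lines changes nothing."""
    split = [LineMeta(f"L{i}", 1, divisions, s, 0) for i, s in enumerate(sites)]
    merged = [LineMeta("all", 1, divisions, sum(sites), 0)]
    a = estimate_rate(n, split)
    b = estimate_rate(n, merged)
    assert a.rate == pytest.approx(b.rate, rel=1e-12)
    assert a.ci == pytest.approx(b.ci, rel=1e-12)


def test_exposure_requires_known_site_class():
    with pytest.raises(ValueError):
        exposure([_one_line(10, 10)], "XY")
    with pytest.raises(ValueError):
        estimate_rate(1, [_one_line(10, 0)], "GC")  # zero G/C exposure


def test_conditional_rates_hand_example():
    """u over A/T exposure, v over G/C exposure; m = u/v."""
    spectrum = SpectrumCounts({
        MutationClass.AT_TO_GC: 2,
        MutationClass.AT_TO_CG: 1,
        MutationClass.GC_TO_AT: 12,
        MutationClass.GC_TO_TA: 6,
    })
    lines = [_one_line(3000, 1000, divisions=1.0)]  # A/T exposure 3x G/C
    cond = conditional_rates(spectrum, lines)
    assert cond.u == pytest.approx(3 / 3000)
    assert cond.v == pytest.approx(18 / 1000)
    assert cond.m == pytest.approx(1 / 18)


def test_conditional_rates_ignore_pair_conserving_classes():
    spectrum = SpectrumCounts({
        MutationClass.AT_TO_TA: 7,
        MutationClass.GC_TO_CG: 5,
        MutationClass.GC_TO_AT: 1,
    })
    cond = conditional_rates(spectrum, [_one_line(1000, 1000, 1.0)])
    assert cond.u == 0.0
    assert cond.m == 0.0


def test_bias_undefined_when_v_zero():
    cond = ConditionalRates(u=1e-12, v=0.0)
    assert cond.m is None


def test_per_class_rates_and_ci_width_shrinks_with_exposure():
    spectrum = SpectrumCounts({MutationClass.GC_TO_AT: 4})
    widths = []
    for divisions in (10.0, 100.0, 1000.0):
        rates = per_class_rates(spectrum, [_one_line(1000, 1000, divisions)])
        est = rates[MutationClass.GC_TO_AT]
        assert est.rate == pytest.approx(4 / (1000 * divisions))
        widths.append(est.ci_high - est.ci_low)
        # classes with zero counts still get the n=0 upper bound
        zero = rates[MutationClass.AT_TO_CG]
        assert zero.rate == 0.0
        assert zero.ci_high == pytest.approx(3.6889 / (1000 * divisions), rel=1e-4)
    assert widths[0] > widths[1] > widths[2]


def test_compare_rates_null_and_enumerated_case():
    assert compare_rates(7, 2.0, 7, 2.0) == 1.0
    # brute-force: P(Bin(5, 0.5) <= 0) = 1/32, doubled
    assert compare_rates(0, 1.0, 5, 1.0) == pytest.approx(0.0625)
    assert compare_rates(5, 1.0, 0, 1.0) == pytest.approx(0.0625)


@pytest.mark.parametrize("n1,n2,e1,e2", [(3, 8, 1.0, 2.0), (10, 2, 5.0, 1.0)])
def test_compare_rates_against_tail_enumeration(n1, n2, e1, e2):
    total, p = n1 + n2, e1 / (e1 + e2)
    pmf = [math.comb(total, k) * p**k * (1 - p) ** (total - k) for k in range(total + 1)]
    lower, upper = sum(pmf[: n1 + 1]), sum(pmf[n1:])
    expected = min(1.0, 2 * min(lower, upper))
    assert compare_rates(n1, e1, n2, e2) == pytest.approx(expected, rel=1e-9)


def test_cell_division_bookkeeping():
    assert cell_divisions(148, 6.6) == pytest.approx(976.8)
    assert cell_divisions(148, 6.6, nearest=10) == 980
    assert cell_divisions(156, 5.1, nearest=10) == 800
    with pytest.raises(ValueError):
        cell_divisions(0, 5.0)


def test_line_meta_validation():
    with pytest.raises(ValueError):
        LineMeta("L1", 10, 5.0, 0, 0)
    with pytest.raises(ValueError):
        LineMeta("L1", -1, 5.0, 10, 10)
    meta = LineMeta("L1", 156, 5.1, 70, 30)
    assert meta.total_divisions == pytest.approx(795.6)
    assert meta.callable_sites == 100
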