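"""Digital-expression Bayesian test, fold changes and DE calling."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from srnakit.diffexpr import (
    LibraryStats, bayes_pvalue, call_differential, de_table, fold_change,
    normalize_counts,
)
from oracles import bayes_pvalue_by_summation

# printed relative-count pairs whose published fold changes are exactly
# consistent at two decimals (library-1 value, library-2 value, fold change)
TABLE1_CONSISTENT_ROWS = [
    ("hsa-miR-222", 290.95, 5977.41, 20.54),
    ("hsa-miR-100", 12.71, 114.53, 9.01),
    ("hsa-miR-30c-2*", 8.09, 65.40, 8.08),
    ("hsa-miR-30a", 17.34, 135.20, 7.80),
    ("hsa-miR-629", 2.31, 16.94, 7.33),
    ("hsa-miR-148b", 18.49, 132.83, 7.18),
    ("hsa-miR-1323", 37.38, 205.69, 5.50),
    ("hsa-miR-301a", 75.15, 3.05, 24.64),
]


def test_normalization_is_reads_per_million():
    assert normalize_counts(np.array([10]), 1_000_000)[0] == pytest.approx(10.0)
    assert normalize_counts(np.array([0]), 12345)[0] == 0.0


def test_relative_counts_sum_to_one_million_per_library():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 5000, size=300)
    rel = normalize_counts(counts, counts.sum())
    assert rel.sum() == pytest.approx(1e6, abs=1e-6)


def test_zero_library_total_rejected():
    with pytest.raises(ValueError):
        normalize_counts(np.array([1]), 0)


def test_equal_counts_equal_depths_give_pvalue_one():
    for x in (0, 1, 7, 250):
        assert bayes_pvalue(x, x, 50_000, 50_000) == pytest.approx(1.0, abs=1e-9)


def test_five_versus_zero_equal_depths_analytic_value():
    # lower tail p(0|5) = C(5,0)/2^6 = 1/64; two-sided doubles it
    assert bayes_pvalue(5, 0, 1e6, 1e6) == pytest.approx(2 / 64, abs=1e-12)


def test_matches_direct_summation_oracle_on_grid():
    rng = np.random.default_rng(42)
    for _ in range(120):
        x = int(rng.integers(0, 150))
        y = int(rng.integers(0, max(1, 200 - x)))
        n1 = float(rng.integers(10_000, 2_000_000))
        n2 = float(rng.integers(10_000, 2_000_000))
        ours = bayes_pvalue(x, y, n1, n2)
        oracle = bayes_pvalue_by_summation(x, y, n1, n2)
        assert ours == pytest.approx(oracle, rel=1e-10, abs=1e-300)


def test_posterior_tail_equals_negative_binomial_form():
    """Cross-check: p(y|x) is the NB(x+1, 1/(1+N2/N1)) predictive."""
    for x, y, n1, n2 in [(12, 3, 1e5, 2e5), (0, 9, 3e5, 1e5), (40, 55, 1e6, 1e6)]:
        tails = []
        for a, b, ratio in ((x, y, n2 / n1), (y, x, n1 / n2)):
            tails.append(float(nbinom.cdf(b, a + 1, 1.0 / (1.0 + ratio))))
            tails.append(float(nbinom.sf(b - 1, a + 1, 1.0 / (1.0 + ratio))))
        expected = min(1.0, 2.0 * min(tails))
        assert bayes_pvalue(x, y, n1, n2) == pytest.approx(expected, rel=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    st.integers(0, 300), st.integers(0, 300),
    st.integers(1_000, 10_000_000), st.integers(1_000, 10_000_000),
)
def test_symmetry_under_library_swap(x, y, n1, n2):
    assert bayes_pvalue(x, y, n1, n2) == pytest.approx(
        bayes_pvalue(y, x, n2, n1), rel=1e-9
    )


def test_upper_tail_shrinks_as_second_count_grows():
    previous = 1.1
    for y in range(20, 200, 20):
        p = bayes_pvalue(20, y, 1e5, 1e5)
        assert p <= previous + 1e-12
        previous = p


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        bayes_pvalue(-1, 3, 1e5, 1e5)


@pytest.mark.parametrize("name,r1,r2,expected", TABLE1_CONSISTENT_ROWS)
def test_fold_change_reproduces_published_relative_count_ratios(name, r1, r2, expected):
    ratio, direction = fold_change(r1, r2)
    assert round(ratio, 2) == pytest.approx(expected, abs=0.011), name
    assert direction == ("up" if r2 > r1 else "down")


def test_fold_change_identity_and_undefined_cases():
    ratio, _ = fold_change(5.0, 5.0)
    assert ratio == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fold_change(0.0, 0.0)


def test_call_thresholds_are_inclusive():
    frame = pd.DataFrame(
        {
            "p_value": [0.001, 1e-6, 0.0011],
            "fold_change": [2.0, 1.9, 50.0],
            "direction": ["up", "up", "down"],
        }
    )
    called = call_differential(frame)
    assert list(called["call"]) == ["up", "unchanged", "unchanged"]


def test_de_table_zero_count_display_and_floor():
    counts = pd.DataFrame(
        {
            "name": ["a", "b"],
            "count_lib1": [100, 0],
            "count_lib2": [0, 100],
        }
    )
    table = de_table(counts, LibraryStats(1000, 1000))
    a = table.set_index("name").loc["a"]
    assert a["rel_lib2"] == 0.0  # display keeps the true zero
    # zero side floored at one raw read: ratio = 100/1
    assert a["fold_change"] == pytest.approx(100.0)
    assert a["direction"] == "down"


def test_type_one_error_controlled_under_null():
    """Equal planted rates: P <= 0.001 in at most 0.5% of miRNAs."""
    rng = np.random.default_rng(2024)
    n_mirnas, depth = 10_000, 100_000
    rates = np.full(n_mirnas, 1.0 / n_mirnas)
    x = rng.multinomial(depth, rates)
    y = rng.multinomial(depth, rates)
    hits = sum(
        bayes_pvalue(int(a), int(b), depth, depth) <= 0.001 for a, b in zip(x, y)
    )
    assert hits / n_mirnas <= 0.005
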