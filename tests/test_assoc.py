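import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epistat.assoc import (DegenerateTableError, Table2x2, bonferroni,
                           chi2_2x2, genotype_chi2_2x3, hwe_chi2,
                           odds_ratio_ci)
from epistat.study_data import GenotypeCounts

cells = st.integers(min_value=0, max_value=500)


def valid_tables(min_cell=0):
    return st.tuples(cells, cells, cells, cells).filter(
        lambda t: min(t) >= min_cell and t[0] + t[1] >= 1 and t[2] + t[3] >= 1)


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def _hwe_oracle(n0, n1, n2):
    """Independent route: scipy chisquare against HWE-expected counts."""
    n = n0 + n1 + n2
    p = (2 * n0 + n1) / (2 * n)
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    return stats.chisquare([n0, n1, n2], expected, ddof=1).statistic


@pytest.mark.parametrize("counts, expected", [
    ((25, 50, 25), 0.0),       # exact HWE proportions
    ((90, 108, 16), 4.59),     # heterozygote excess below the 6.6 trim cutoff
    ((40, 109, 65), 0.23),
])
def test_hwe_chi2_values(counts, expected):
    res = hwe_chi2(GenotypeCounts(*counts))
    assert res.chi2 == pytest.approx(expected, abs=5e-3)
    assert res.chi2 == pytest.approx(_hwe_oracle(*counts), abs=1e-9)
    assert res.df == 1


def test_hwe_monomorphic_is_undefined():
    with pytest.raises(DegenerateTableError):
        hwe_chi2(GenotypeCounts(50, 0, 0))


# ---------------------------------------------------------------------------
# 2x3 genotype association
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("case, ctrl, expected", [
    ((97, 52, 7), (90, 108, 16), 14.65),
    ((17, 79, 60), (40, 109, 65), 5.31),
])
def test_genotype_chi2_2x3_values(case, ctrl, expected):
    res = genotype_chi2_2x3(GenotypeCounts(*case), GenotypeCounts(*ctrl))
    oracle = stats.chi2_contingency(np.array([case, ctrl]), correction=False)
    assert res.chi2 == pytest.approx(expected, abs=0.01)
    assert res.chi2 == pytest.approx(oracle.statistic, abs=1e-9)
    assert res.df == 2


def test_genotype_chi2_identical_distributions_zero():
    res = genotype_chi2_2x3(GenotypeCounts(30, 20, 10), GenotypeCounts(60, 40, 20))
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)


def test_genotype_chi2_drops_empty_class():
    # deletion-type locus: heterozygote class structurally empty
    res = genotype_chi2_2x3(GenotypeCounts(40, 0, 20), GenotypeCounts(50, 0, 10))
    assert res.df == 1


def test_genotype_chi2_needs_two_classes():
    with pytest.raises(DegenerateTableError):
        genotype_chi2_2x3(GenotypeCounts(40, 0, 0), GenotypeCounts(50, 0, 0))


# ---------------------------------------------------------------------------
# 2x2 with conditional corrections
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("table, chi2, corrected", [
    ((18, 74, 43, 66), 9.33, False),   # all cells >= 10 -> plain Pearson
    ((8, 21, 3, 102), 15.31, True),    # min cell 3 -> Yates
    ((10, 10, 10, 10), 0.0, False),
])
def test_chi2_2x2_printed_values(table, chi2, corrected):
    res = chi2_2x2(Table2x2(*table))
    assert res.chi2 == pytest.approx(chi2, abs=5e-3)
    assert res.yates_applied is corrected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(valid_tables())
def test_chi2_2x2_matches_scipy_under_the_rule(t):
    tab = Table2x2(*t)
    if tab.a + tab.c == 0 or tab.b + tab.d == 0:
        return
    res = chi2_2x2(tab)
    oracle = stats.chi2_contingency(tab.as_array(),
                                    correction=tab.min_cell < 10)
    assert res.chi2 == pytest.approx(oracle.statistic, abs=1e-9)
    assert res.p == pytest.approx(oracle.pvalue, abs=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(valid_tables())
def test_yates_never_exceeds_pearson(t):
    tab = Table2x2(*t)
    if tab.a + tab.c == 0 or tab.b + tab.d == 0:
        return
    plain = chi2_2x2(tab, small_cell_threshold=0).chi2
    corrected = chi2_2x2(tab, small_cell_threshold=10 ** 9).chi2
    assert corrected <= plain + 1e-12
    assert plain >= 0.0


def test_chi2_monte_carlo_agreement():
    """Chi-square p agrees with a label-permutation null (+-3 SE).

    The permutation null (both margins fixed) is discrete, so the asymptotic
    p is compared against the Monte-Carlo *mid-p* (half weight on the
    observed atom), which is what the continuous chi-square distribution
    approximates.
    """
    rng = np.random.default_rng(7)
    for _ in range(5):
        t = Table2x2(*rng.integers(100, 400, size=4))
        n1, n = t.a + t.b, t.n
        k = t.a + t.c
        draws = rng.hypergeometric(n1, n - n1, k, size=20_000)
        vals = np.unique(draws)
        chis = np.array([chi2_2x2(Table2x2(int(a), int(n1 - a), int(k - a),
                                           int(n - n1 - k + a)),
                                  small_cell_threshold=0).chi2
                         for a in vals])
        weights = np.array([(draws == a).sum() for a in vals])
        plain = chi2_2x2(t, small_cell_threshold=0).chi2
        above = weights[chis > plain + 1e-9].sum()
        atom = weights[np.abs(chis - plain) <= 1e-9].sum()
        mc_mid_p = (above + 0.5 * atom) / weights.sum()
        se = np.sqrt(max(mc_mid_p * (1 - mc_mid_p), 1e-4) / 20_000)
        plain_p = stats.chi2.sf(plain, 1)
        assert abs(mc_mid_p - plain_p) <= 3 * se + 0.015


@pytest.mark.parametrize("table, or_val, lo, hi, corrected", [
    ((18, 74, 43, 66), 0.37, 0.20, 0.71, False),
    ((8, 21, 3, 102), 11.58, 3.07, 43.72, True),
    ((5, 24, 1, 104), 15.64, 2.44, 100.3, True),
])
def test_odds_ratio_printed_values(table, or_val, lo, hi, corrected):
    res = odds_ratio_ci(Table2x2(*table))
    assert res.or_value == pytest.approx(or_val, abs=5e-3)
    assert res.ci_low == pytest.approx(lo, abs=0.01)
    assert res.ci_high == pytest.approx(hi, abs=0.1 if hi > 20 else 0.01)
    assert res.haldane_applied is corrected
    assert res.ci_low <= res.or_value <= res.ci_high


@pytest.mark.parametrize("k", [10, 25, 100])
def test_symmetric_table_gives_unit_odds_ratio(k):
    assert odds_ratio_ci(Table2x2(k, k, k, k)).or_value == pytest.approx(1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(valid_tables(min_cell=1))
def test_odds_ratio_swap_symmetries(t):
    a, b, c, d = t
    base = odds_ratio_ci(Table2x2(a, b, c, d))
    both = odds_ratio_ci(Table2x2(d, c, b, a))  # both dimensions swapped
    assert both.or_value == pytest.approx(base.or_value, rel=1e-12)
    rows = odds_ratio_ci(Table2x2(c, d, a, b))  # one dimension swapped
    assert rows.or_value == pytest.approx(1 / base.or_value, rel=1e-12)
    assert rows.ci_low == pytest.approx(1 / base.ci_high, rel=1e-9)
    assert rows.ci_high == pytest.approx(1 / base.ci_low, rel=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(valid_tables(min_cell=1), st.integers(min_value=1, max_value=200))
def test_corrected_and_plain_or_converge(t, scale):
    t = tuple(x * scale for x in t)
    plain = odds_ratio_ci(Table2x2(*t), small_cell_threshold=0).or_value
    corrected = odds_ratio_ci(Table2x2(*t), small_cell_threshold=10 ** 9).or_value
    assert abs(corrected - plain) <= 4 * plain / min(t)


def test_zero_cell_forces_correction():
    with pytest.warns(UserWarning, match="Haldane"):
        res = odds_ratio_ci(Table2x2(20, 20, 0, 40), small_cell_threshold=0)
    assert res.haldane_applied
    assert np.isfinite(res.or_value)


@pytest.mark.parametrize("p, m, expected", [
    (0.0001, 40, 0.004),   # the single-locus result's family of 40 tests
    (0.5, 3, 1.0),
    (0.01, 1, 0.01),
])
def test_bonferroni(p, m, expected):
    assert bonferroni(p, m) == pytest.approx(expected)
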