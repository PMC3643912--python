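"""Exact two-library test, FDR adjustment and log2 ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from digseg import (
    ValidationError,
    audic_logpmf,
    audic_pvalue,
    bh_fdr,
    log2_ratio,
    log2_ratios,
)
from digseg.detest import test_stage as run_stage_test
from conftest import exact_two_sided_p


# ---------------------------------------------------------------------------
# audic_pvalue


@pytest.mark.parametrize(
    "x,y,n1,n2,expected",
    [
        (0, 0, 10**6, 10**6, 1.0),
        (10, 0, 10**6, 10**6, 2**-10),  # P(0|x) = 2^-(x+1) for equal sizes
        (0, 10, 10**6, 10**6, 2**-10),
        (5, 5, 10**6, 10**6, 1.0),      # identical counts, identical depths
    ],
)
def test_analytic_pvalues(x, y, n1, n2, expected):
    assert audic_pvalue(x, y, n1, n2) == pytest.approx(expected, rel=1e-12)


def test_matches_exact_rational_summation_on_spot_tuples():
    for x, y, n1, n2 in [(3, 12, 2_000_000, 1_000_000),
                         (40, 7, 1_000_000, 3_000_000),
                         (0, 25, 5, 7)]:
        exact = float(exact_two_sided_p(x, y, n1, n2))
        assert audic_pvalue(x, y, n1, n2) == pytest.approx(exact, rel=1e-10)


def test_matches_exact_rational_summation_on_small_grid():
    for n1, n2 in [(2, 1), (1, 1), (1, 2)]:
        for x in range(0, 41, 8):
            for y in range(0, 41, 5):
                exact = float(exact_two_sided_p(x, y, n1, n2))
                assert audic_pvalue(x, y, n1, n2) == pytest.approx(
                    exact, rel=1e-10
                ), (x, y, n1, n2)


def test_matches_negative_binomial_tail_route():
    # Independent route: the conditional law is NB(x+1, n1/(n1+n2)) in y.
    rng = np.random.default_rng(3)
    for _ in range(200):
        x, y = (int(v) for v in rng.integers(0, 300, 2))
        n1, n2 = (int(v) for v in rng.integers(1, 10**7, 2))
        lower = nbinom.cdf(y, x + 1, n1 / (n1 + n2))
        upper = nbinom.sf(y, x + 1, n1 / (n1 + n2))
        expected = min(1.0, 2 * min(lower, upper))
        assert audic_pvalue(x, y, n1, n2) == pytest.approx(
            max(expected, 5e-324), rel=1e-8, abs=1e-300
        )


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    x=st.integers(0, 500),
    y=st.integers(0, 500),
    n1=st.integers(1, 10**8),
    n2=st.integers(1, 10**8),
)
def test_symmetry_under_library_exchange(x, y, n1, n2):
    a = audic_pvalue(x, y, n1, n2)
    b = audic_pvalue(y, x, n2, n1)
    assert abs(a - b) < 1e-10


def test_conditional_distribution_normalises():
    for x, n1, n2 in [(0, 10**6, 10**6), (17, 10**6, 2 * 10**6),
                      (100, 3 * 10**6, 10**6)]:
        kmax = int(50 * (x + 1) * max(1, n2 / n1))
        total = np.exp(audic_logpmf(np.arange(kmax + 1), x, n1, n2)).sum()
        assert total >= 1 - 1e-9
        assert total <= 1 + 1e-9


def test_pvalue_decreases_away_from_the_mode():
    x, n = 20, 10**6
    above = [audic_pvalue(x, y, n, n) for y in range(21, 60, 4)]
    assert all(a > b for a, b in zip(above, above[1:]))
    below = [audic_pvalue(x, y, n, n) for y in range(19, 0, -4)]
    assert all(a > b for a, b in zip(below, below[1:]))


def test_pvalue_validates_inputs():
    with pytest.raises(ValidationError):
        audic_pvalue(-1, 0, 10, 10)
    with pytest.raises(ValidationError):
        audic_pvalue(0, 0, 0, 10)


def test_extreme_counts_do_not_underflow_to_zero():
    p = audic_pvalue(5000, 0, 10**6, 10**6)
    assert 0 < p <= 1


# ---------------------------------------------------------------------------
# bh_fdr


def _brute_force_bh(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def test_bh_worked_examples():
    assert bh_fdr([0.005]) == pytest.approx([0.005])
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=60)
)
def test_bh_matches_quadratic_step_up_definition(p):
    q = bh_fdr(p)
    assert np.allclose(q, _brute_force_bh(np.asarray(p)), rtol=1e-12)
    assert (q >= np.asarray(p) - 1e-15).all()
    assert (q <= 1.0).all()


def test_bh_equal_pvalues_share_a_q_value():
    q = bh_fdr([0.02, 0.02, 0.5])
    assert q[0] == q[1]


def test_by_is_more_conservative_than_bh():
    p = [0.001, 0.01, 0.04, 0.2, 0.9]
    assert (bh_fdr(p, method="by") >= bh_fdr(p, method="bh")).all()


def test_bh_rejects_out_of_range_pvalues():
    for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
        with pytest.raises(ValidationError):
            bh_fdr(bad)
    with pytest.raises(ValidationError):
        bh_fdr([0.5], method="bonferroni-ish")


# ---------------------------------------------------------------------------
# log2_ratio


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (7.3, 7.3, 0.0),
        (66.32, 2.92, 4.5054),   # strongly female-biased transcript at 90 dah
        (5.0, 0.0, math.inf),
        (0.0, 5.0, -math.inf),
    ],
)
def test_log2_ratio_examples(a, b, expected):
    assert log2_ratio(a, b) == pytest.approx(expected, abs=1e-4)


def test_log2_ratio_undefined_when_both_zero():
    assert math.isnan(log2_ratio(0.0, 0.0))
    with pytest.raises(ValidationError):
        log2_ratio(-1.0, 2.0)


def test_vectorised_ratios_agree_with_scalar():
    a = np.array([7.3, 66.32, 5.0, 0.0, 0.0])
    b = np.array([7.3, 2.92, 0.0, 5.0, 0.0])
    vec = log2_ratios(a, b)
    for i in range(len(a)):
        s = log2_ratio(a[i], b[i])
        assert (math.isnan(s) and math.isnan(vec[i])) or s == vec[i]


# ---------------------------------------------------------------------------
# test_stage


def _stage_inputs():
    genes = pd.Index(["g_eq", "g_up", "g_down", "g_xxonly", "g_off"],
                     name="gene_id")
    counts = pd.DataFrame(
        {"XX_5": [50, 400, 30, 80, 0], "XY_5": [50, 40, 300, 0, 0]},
        index=genes,
    )
    libraries = pd.DataFrame(
        {"group": ["XX", "XY"], "stage": ["5", "5"],
         "total_mapped_reads": [10**6, 10**6]},
        index=pd.Index(["XX_5", "XY_5"], name="library_id"),
    )
    lengths = pd.DataFrame({"length": [1000] * 5}, index=genes)
    from digseg import compute_rpkm

    rpkm = compute_rpkm(counts, lengths, libraries)
    return counts, rpkm, libraries


def test_stage_pairwise_results():
    counts, rpkm, libraries = _stage_inputs()
    res = run_stage_test(counts, rpkm, libraries, "5")
    assert list(res.index) == ["g_eq", "g_up", "g_down", "g_xxonly"]
    assert res.loc["g_eq", "p_value"] == pytest.approx(1.0)
    assert res.loc["g_up", "log2_ratio"] > 1
    assert res.loc["g_down", "q_value"] <= 1e-2
    assert res.loc["g_xxonly", "log2_ratio"] == math.inf
    # q from BH over exactly the four tested genes
    assert np.allclose(
        res["q_value"], bh_fdr(res["p_value"].to_numpy()), rtol=1e-12
    )


def test_stage_validates_design():
    counts, rpkm, libraries = _stage_inputs()
    with pytest.raises(ValidationError):
        run_stage_test(counts, rpkm, libraries, "90")
    dup = pd.concat([libraries, libraries.rename(index={"XX_5": "XX_5b"})])
    dup = dup[~dup.index.duplicated()]
    with pytest.raises(ValidationError):
        run_stage_test(counts, rpkm, dup, "5")
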