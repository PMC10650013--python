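import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaqueindex import (
    ApiCategory,
    categorize_api,
    ckd_epi_egfr,
    classify_ckd,
    delta_pct_egfr,
    empirical_roc,
    fisher_exact,
    fit_logistic,
    mann_whitney,
    odds_ratio_2x2,
)
from plaqueindex.clinical import ClinicalError


# ---------------------------------------------------------------------------
# enumeration oracles (independent of the implementations under test)


def mw_exact_p_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    nx = len(x)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by construction

    def u_of(idx):
        rank_sum = sum(ranks[pooled[i]] for i in idx)
        return rank_sum - nx * (nx + 1) / 2

    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    mean_u = nx * len(y) / 2
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), nx)]
    extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12 for u in us)
    return extreme / len(us)


def fisher_p_oracle(table):
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa):
        return (math.comb(r1, aa) * math.comb(r2, c1 - aa)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(aa) for aa in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(aa) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# formulas


@pytest.mark.parametrize(
    "cr,age,sex,expected",
    [
        # frozen hand evaluations of the published piecewise formula
        (0.7, 60, "female", 94.1720),   # 141*1.018*0.993^60, ratio term 1 at the knot
        (0.9, 60, "male", 92.5069),     # 141*0.993^60
        (1.4, 70, "male", 50.5448),     # 141*(1.4/0.9)^-1.209*0.993^70
        (0.5, 45, "female", 116.8851),  # 141*1.018*(0.5/0.7)^-0.329*0.993^45
    ],
)
def test_ckd_epi_matches_hand_evaluated_formula(cr, age, sex, expected):
    assert ckd_epi_egfr(cr, age, sex) == pytest.approx(expected, abs=0.1)


def test_ckd_epi_race_flag_and_errors():
    base = ckd_epi_egfr(1.0, 50, "male")
    assert ckd_epi_egfr(1.0, 50, "male", black=True) == pytest.approx(base * 1.159)
    with pytest.raises(ClinicalError):
        ckd_epi_egfr(0.0, 50, "male")
    with pytest.raises(ClinicalError):
        ckd_epi_egfr(1.0, -1, "female")


@pytest.mark.parametrize("pre,last,expected", [
    (100.0, 90.0, -10.0),
    (88.5, 88.5, 0.0),
    (88.5, 85.7, -3.164),
])
def test_delta_pct_egfr_direct_arithmetic(pre, last, expected):
    assert delta_pct_egfr(pre, last) == pytest.approx(expected, abs=5e-4)


def test_delta_pct_egfr_rejects_nonpositive_baseline():
    with pytest.raises(ClinicalError):
        delta_pct_egfr(0.0, 50.0)


def test_ckd_threshold_boundary_and_override():
    assert classify_ckd(59.9) is True
    assert classify_ckd(60.0) is False
    assert classify_ckd(88.5) is False
    assert classify_ckd(50.0, threshold=45.0) is False
    with pytest.raises(ClinicalError):
        classify_ckd(0.0)


@pytest.mark.parametrize("api,cat", [
    (0.0, ApiCategory.ZERO),
    (2.1, ApiCategory.POSITIVE_LT10),
    (9.999, ApiCategory.POSITIVE_LT10),
    (10.0, ApiCategory.GE10),
    (55.0, ApiCategory.GE10),
])
def test_api_categorisation(api, cat):
    assert categorize_api(api) is cat


def test_api_categorisation_rejects_negative():
    with pytest.raises(ClinicalError):
        categorize_api(-0.1)


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mw_tiny_example_matches_enumeration():
    res = mann_whitney([1, 2], [3, 4])
    assert res.statistic == 0
    assert res.method == "mann-whitney-exact"
    assert res.p_value == pytest.approx(2 / 6, abs=1e-12)


def test_mw_identical_samples_p_near_one():
    res = mann_whitney([1, 2, 3, 4, 5], [1.5, 2.5, 3.5, 4.5, 0.5])
    assert res.p_value >= 0.5  # symmetric interleave
    res2 = mann_whitney([1, 3, 5], [2, 4, 6])
    assert res2.p_value >= 0.5


@given(nx=st.integers(2, 5), ny=st.integers(2, 5), data=st.data())
@settings(max_examples=30)
def test_mw_exact_branch_matches_permutation_oracle(nx, ny, data):
    vals = data.draw(st.lists(st.floats(-100, 100, allow_nan=False),
                              min_size=nx + ny, max_size=nx + ny, unique=True))
    x, y = vals[:nx], vals[nx:]
    res = mann_whitney(x, y)
    assert res.method == "mann-whitney-exact"
    assert res.p_value == pytest.approx(mw_exact_p_oracle(x, y), abs=1e-9)


def test_mw_falls_back_to_tie_corrected_normal():
    res = mann_whitney([1, 1, 2, 2, 3], [2, 3, 3, 4, 4])
    assert res.method == "mann-whitney-normal"
    assert 0 < res.p_value < 1
    with pytest.raises(ClinicalError):
        mann_whitney([], [1])


# ---------------------------------------------------------------------------
# Fisher / odds ratios


def test_fisher_small_tables_match_enumeration():
    assert fisher_exact([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3, abs=1e-12)
    assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)


@given(a=st.integers(0, 6), b=st.integers(0, 6), c=st.integers(0, 6), d=st.integers(0, 6))
@settings(max_examples=60)
def test_fisher_matches_enumeration_oracle(a, b, c, d):
    t = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        with pytest.raises(ClinicalError):
            fisher_exact(t)
        return
    assert fisher_exact(t).p_value == pytest.approx(fisher_p_oracle(t), abs=1e-9)


def test_odds_ratio_arithmetic_and_symmetry():
    assert odds_ratio_2x2([[10, 10], [10, 10]]).odds_ratio == pytest.approx(1.0)
    res = odds_ratio_2x2([[20, 5], [5, 20]])
    assert res.odds_ratio == pytest.approx(16.0)
    assert res.ci_low < 16.0 < res.ci_high
    flipped = odds_ratio_2x2([[5, 20], [20, 5]])
    assert flipped.odds_ratio == pytest.approx(1 / 16.0)
    corr = odds_ratio_2x2([[5, 0], [2, 7]])
    assert corr.corrected


# ---------------------------------------------------------------------------
# logistic regression


def _cohort_from_counts(a, b, c, d):
    """Rows for a 2x2 design: exposure x outcome counts (a=exp/out ...)."""
    rows = ([{"x": 1, "y": 1}] * a + [{"x": 1, "y": 0}] * b
            + [{"x": 0, "y": 1}] * c + [{"x": 0, "y": 0}] * d)
    return pd.DataFrame(rows)


def test_saturated_logistic_reproduces_cross_product_or():
    df = _cohort_from_counts(20, 5, 5, 20)
    fit = fit_logistic(df, "y", ["x"])
    assert fit.converged
    assert fit.odds_ratio("x") == pytest.approx(16.0, rel=1e-6)  # 6 s.f.
    assert 0 < fit.pseudo_r2 < 1


def test_constant_covariate_dropped_with_flag_not_nan():
    df = _cohort_from_counts(20, 5, 5, 20)
    df["z"] = 0.0
    fit = fit_logistic(df, "y", ["x", "z"])
    assert any("z" in f for f in fit.flags)
    assert "z" not in fit.table.index
    assert np.isfinite(fit.table["coef"]).all()


def test_single_class_outcome_rejected():
    df = _cohort_from_counts(20, 5, 0, 0)
    df["y"] = 1
    with pytest.raises(ClinicalError, match="binary"):
        fit_logistic(df, "y", ["x"])


def test_separation_is_flagged():
    df = _cohort_from_counts(20, 0, 0, 20)
    fit = fit_logistic(df, "y", ["x"])
    assert not fit.converged or fit.flags


def test_api_covariate_expands_to_category_indicators():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "api": np.r_[np.zeros(40), rng.uniform(0.5, 9, 40), rng.uniform(10, 30, 40)],
        "y": np.r_[rng.random(40) < 0.2, rng.random(40) < 0.4, rng.random(40) < 0.8].astype(int),
    })
    fit = fit_logistic(df, "y", ["api"])
    assert {"api_lt10", "api_ge10"} <= set(fit.table.index)


# ---------------------------------------------------------------------------
# empirical ROC


def test_roc_perfect_separation_and_null():
    assert empirical_roc([0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == pytest.approx(1.0)
    rng = np.random.default_rng(1)
    auc = empirical_roc(rng.normal(size=4000), rng.integers(0, 2, 4000)).auc
    assert auc == pytest.approx(0.5, abs=0.03)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=20)
def test_roc_auc_equals_scaled_mann_whitney_u(seed):
    rng = np.random.default_rng(seed)
    n1, n0 = rng.integers(5, 30, 2)
    cases = rng.normal(1, 1, n1)
    controls = rng.normal(0, 1, n0)
    auc = empirical_roc(np.r_[controls, cases], np.r_[np.zeros(n0), np.ones(n1)]).auc
    u_cases = mann_whitney(cases, controls).statistic
    assert auc == pytest.approx(u_cases / (n1 * n0), abs=1e-9)
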