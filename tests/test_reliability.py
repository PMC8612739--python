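"""Kappa statistics and RT agreement against hand computations and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audiotactile.reliability import (
    AgreementTable,
    DegenerateTableError,
    agreement_table,
    cohen_kappa,
    rt_agreement,
    weighted_kappa,
)


def test_perfect_agreement():
    tab = AgreementTable([[25, 0], [0, 25]], ["L", "R"])
    assert cohen_kappa(tab).kappa == pytest.approx(1.0)
    assert weighted_kappa(tab, "linear").kappa == pytest.approx(1.0)
    assert weighted_kappa(tab, "quadratic").kappa == pytest.approx(1.0)


def test_worked_example_kappa_04():
    # p_o = 35/50 = 0.7; p_e = 0.6*0.5 + 0.4*0.5 = 0.5; kappa = 0.2/0.5 = 0.4
    tab = AgreementTable([[20, 5], [10, 15]], ["L", "R"])
    res = cohen_kappa(tab)
    assert res.kappa == pytest.approx(0.4)
    assert res.ci_low <= res.kappa <= res.ci_high


def test_independent_rows_give_zero():
    # identical rows: rater 2's marginal is independent of rater 1
    tab = AgreementTable([[9, 3], [9, 3]], ["L", "R"])
    assert cohen_kappa(tab).kappa == pytest.approx(0.0)


def test_binary_weighted_equals_unweighted():
    tab = AgreementTable([[20, 5], [10, 15]], ["L", "R"])
    for scheme in ("linear", "quadratic"):
        assert weighted_kappa(tab, scheme).kappa == pytest.approx(cohen_kappa(tab).kappa)


def test_weighted_kappa_matches_cell_sum_oracle():
    counts = np.array([[10.0, 2, 0], [2, 10, 2], [0, 2, 10]])
    tab = AgreementTable(counts, ["a", "b", "c"])
    # independent summation oracle over all cells
    n = counts.sum()
    p = counts / n
    pi, pj = p.sum(1), p.sum(0)
    k = 3
    w = 1.0 - np.abs(np.subtract.outer(range(k), range(k))) / (k - 1)
    po = sum(w[i, j] * p[i, j] for i in range(k) for j in range(k))
    pe = sum(w[i, j] * pi[i] * pj[j] for i in range(k) for j in range(k))
    expected = (po - pe) / (1 - pe)
    assert weighted_kappa(tab, "linear").kappa == pytest.approx(expected, abs=1e-12)


def test_matches_statsmodels_oracle():
    import statsmodels.stats.inter_rater as ir

    rng = np.random.default_rng(0)
    for _ in range(5):
        counts = rng.integers(0, 30, (3, 3)).astype(float) + 1
        tab = AgreementTable(counts, ["a", "b", "c"])
        ref = ir.cohens_kappa(counts)
        mine = cohen_kappa(tab)
        assert mine.kappa == pytest.approx(ref.kappa, abs=1e-10)
        assert mine.ci_low == pytest.approx(ref.kappa_low, abs=1e-6)
        assert mine.ci_high == pytest.approx(ref.kappa_upp, abs=1e-6)
        for scheme in ("linear", "quadratic"):
            ref_w = ir.cohens_kappa(counts, wt="linear" if scheme == "linear" else "quadratic")
            assert weighted_kappa(tab, scheme).kappa == pytest.approx(ref_w.kappa, abs=1e-10)


def test_degenerate_marginals_error():
    tab = AgreementTable([[10, 0], [0, 0]], ["L", "R"])
    with pytest.raises(DegenerateTableError):
        cohen_kappa(tab)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.permutations(range(3)), st.integers(0, 2**31 - 1))
def test_kappa_invariant_to_joint_relabeling(perm, seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 20, (3, 3)).astype(float)
    perm = list(perm)
    k1 = cohen_kappa(AgreementTable(counts, ["a", "b", "c"])).kappa
    k2 = cohen_kappa(AgreementTable(counts[np.ix_(perm, perm)], ["a", "b", "c"])).kappa
    assert k1 == pytest.approx(k2, abs=1e-12)


def test_rt_agreement_identity_and_offset():
    rt1 = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
    res = rt_agreement(rt1, rt1)
    assert res.pearson_r == pytest.approx(1.0)
    assert res.mean_signed_diff_s == pytest.approx(0.0)
    res = rt_agreement(rt1, rt1 + 0.04)
    assert res.mean_signed_diff_s == pytest.approx(-0.04)


def test_rt_agreement_matches_covariance_formula_oracle():
    rng = np.random.default_rng(1)
    rt1 = rng.gamma(4, 0.5, 800)
    rt2 = rt1 + rng.normal(0, 0.1, 800)
    res = rt_agreement(rt1, rt2)
    x, y = rt1 - rt1.mean(), rt2 - rt2.mean()
    oracle = (x @ y) / np.sqrt((x @ x) * (y @ y))
    assert res.pearson_r == pytest.approx(oracle, abs=1e-12)
    assert res.r_ci[0] < res.pearson_r < res.r_ci[1]


def test_rt_agreement_errors():
    with pytest.raises(ValueError, match="zero variance"):
        rt_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="at least 3"):
        rt_agreement([1.0, 2.0], [1.0, 2.0])
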