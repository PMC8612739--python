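"""Quantile machinery and redundancy-gain tests for the race-model analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audiotactile.race import (
    DECILES,
    EmptyCellError,
    _welch_df,
    participant_quantiles,
    race_bound_quantiles,
    redundancy_gain,
)
from audiotactile.trials import SCHEMA


def _scan_quantile(values, q):
    """Brute-force inverse-CDF oracle: smallest x with F(x) >= q."""
    xs = sorted(values)
    n = len(xs)
    for x in xs:
        if sum(v <= x for v in xs) / n >= q - 1e-12:
            return x
    return xs[-1]


def _scan_bound_quantile(rt_a, rt_t, q):
    """Brute-force oracle for the summed-CDF bound on the pooled support."""
    support = sorted(set(rt_a) | set(rt_t))
    for x in support:
        fa = sum(v <= x for v in rt_a) / len(rt_a)
        ft = sum(v <= x for v in rt_t) / len(rt_t)
        if min(1.0, fa + ft) >= q - 1e-12:
            return x
    return support[-1]


def test_singleton_and_odd_median():
    assert participant_quantiles([2.0], [0.1, 0.5, 0.9]).rt_at_prob.tolist() == [2, 2, 2]
    prof = participant_quantiles([1, 2, 3, 4, 5], [0.5])
    assert prof.rt_at_prob[0] == 3.0


def test_deciles_match_scan_oracle():
    rng = np.random.default_rng(0)
    rts = rng.uniform(0.5, 4.0, 20)
    prof = participant_quantiles(rts, DECILES)
    for q, v in zip(DECILES, prof.rt_at_prob):
        assert v == pytest.approx(_scan_quantile(rts, q))


def test_bound_hand_example():
    # G(2) = F_A(2) + F_T(2) = 0.5 + 0 = 0.5, so the median of the bound is 2
    prof = race_bound_quantiles([2.0, 4.0], [3.0, 5.0], [0.5])
    assert prof.rt_at_prob[0] == 2.0


def test_bound_low_deciles_equal_doubled_mass():
    """When every tactile RT exceeds max auditory RT, the bound over the
    auditory range is F_A alone — each auditory RT carrying twice its pooled
    (1/(n_A+n_T)) mass — so every decile is an F_A quantile."""
    rng = np.random.default_rng(1)
    rt_a = np.sort(rng.uniform(0.5, 1.5, 8))
    rt_t = rng.uniform(2.0, 3.0, 8)
    prof = race_bound_quantiles(rt_a, rt_t, DECILES)
    for q, v in zip(DECILES, prof.rt_at_prob):
        assert v == pytest.approx(_scan_bound_quantile(rt_a, rt_t, q))
        assert v == pytest.approx(_scan_quantile(rt_a, q))


def test_identical_lists_halve_the_probability():
    rts = [0.8, 1.1, 1.6, 2.2, 3.0]
    prof = race_bound_quantiles(rts, rts, [0.2, 0.4, 0.8])
    for q, v in zip([0.2, 0.4, 0.8], prof.rt_at_prob):
        assert v == pytest.approx(_scan_quantile(rts, q / 2))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(0.1, 8.0), min_size=1, max_size=15),
    st.lists(st.floats(0.1, 8.0), min_size=1, max_size=15),
)
def test_bound_dominates_unisensory_quantiles(rt_a, rt_t):
    bound = race_bound_quantiles(rt_a, rt_t, DECILES).rt_at_prob
    qa = participant_quantiles(rt_a, DECILES).rt_at_prob
    qt = participant_quantiles(rt_t, DECILES).rt_at_prob
    assert (bound <= np.minimum(qa, qt) + 1e-12).all()
    assert (np.diff(bound) >= -1e-12).all()  # monotone in q


def _gain_frame(per_participant_rts):
    """Build a minimal trial table from {pid: {cond: [rts]}} (uncrossed, S/SVI)."""
    rows = []
    cmap = {"A": ("auditory_only", "none", "left"), "T": ("tactile_only", "left", "none"),
            "AT": ("at_congruent", "left", "left")}
    for pid, cells in per_participant_rts.items():
        group = "SVI" if pid.startswith("v") else "S"
        for cond, rts in cells.items():
            cname, t_side, a_side = cmap[cond]
            for rt in rts:
                rows.append((pid, group, 15, 1, "uncrossed", cname, t_side, a_side,
                             "arm_hand", "left", rt, True))
    return pd.DataFrame(rows, columns=SCHEMA)


def test_gain_zero_when_at_equals_bound():
    """Feeding each participant's bound deciles back as their AT RTs gives
    gain exactly 0 at every decile and no rejections."""
    rng = np.random.default_rng(2)
    data = {}
    for i in range(6):
        rt_a = list(np.round(rng.uniform(0.5, 3.0, 6), 3))
        rt_t = list(np.round(rng.uniform(0.5, 3.0, 6), 3))
        bound = race_bound_quantiles(rt_a, rt_t, DECILES).rt_at_prob
        data[f"s{i}"] = {"A": rt_a, "T": rt_t, "AT": list(bound)}
    table = redundancy_gain(_gain_frame(data))
    assert np.allclose(table.gains["mean_gain_s"], 0.0)
    assert not table.gains["significant"].any()


def test_group_mean_equals_transposed_aggregation(default_trials):
    from audiotactile.trials import filter_trials

    analysed, _ = filter_trials(default_trials)
    table = redundancy_gain(analysed)
    per = table.per_participant
    for _, r in table.gains.iterrows():
        sub = per[(per.group == r["group"]) & (per.posture == r["posture"])
                  & (per.decile == r["decile"])]
        # transposed: average each participant's (single) decile value first
        transposed = sub.groupby("participant_id")["gain_s"].mean().mean()
        assert r["mean_gain_s"] == pytest.approx(transposed, abs=1e-12)


def test_missing_cell_drops_participant():
    data = {
        "s0": {"A": [1.0, 2.0], "T": [1.5, 2.5], "AT": [0.9, 1.1]},
        "s1": {"A": [1.0], "T": [1.2], "AT": [0.8]},
        "s2": {"A": [1.1, 1.3], "T": [1.4], "AT": [1.0]},
        "v0": {"A": [1.0], "AT": [0.9]},  # no tactile cell -> dropped
    }
    table = redundancy_gain(_gain_frame(data))
    assert ("v0", "uncrossed") in table.dropped
    assert set(table.per_participant.participant_id) == {"s0", "s1", "s2"}
    # fewer than 2 SVI participants -> no SVI rows, no group comparison
    assert (table.gains.group == "S").all()
    assert table.group_tests.empty


def test_welch_df_fractional():
    x1 = np.array([41.0, 45, 47, 44, 46, 43, 48, 42, 45, 44])
    x2 = np.array([39.0, 40, 38, 41, 37, 42, 36, 40, 39, 38])
    df = _welch_df(x1, x2)
    assert 2 < df < len(x1) + len(x2) - 2 + 1e-9
    assert df != int(df)  # fractional in general
    # against scipy's own Welch machinery
    from scipy import stats

    res = stats.ttest_ind(x1, x2, equal_var=False)
    assert res.df == pytest.approx(df)


def test_empty_rt_list_raises():
    with pytest.raises(EmptyCellError):
        participant_quantiles([], DECILES)
    with pytest.raises(EmptyCellError):
        race_bound_quantiles([], [1.0], DECILES)
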