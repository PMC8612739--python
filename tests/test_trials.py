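"""Schedule generation, trial I/O, reconciliation and filtering."""


import numpy as np
import pandas as pd
import pytest

from audiotactile.simulate import SimConfig, simulate_dataset, simulate_raters
from audiotactile.trials import (
    SCHEMA,
    SchemaError,
    ValidationError,
    check_schedule,
    filter_trials,
    make_schedule,
    read_trials,
    reconcile_ratings,
    response_outcome,
    validate_trials,
    write_trials,
)


def _scan_max_run(df: pd.DataFrame) -> int:
    """Independent brute-force scan for the longest same-hand same-cue run."""
    events = []
    for _, r in df.iterrows():
        keys = set()
        if r["tactile_side"] != "none":
            keys.add((r["tactile_side"], "tactile"))
        if r["auditory_side"] != "none":
            keys.add((r["auditory_side"], "auditory"))
        events.append(keys)
    best = 0
    for key in {k for e in events for k in e}:
        run = 0
        for e in events:
            run = run + 1 if key in e else 0
            best = max(best, run)
    return best


@pytest.mark.parametrize("seed", range(40))
def test_schedule_satisfies_all_design_constraints(seed):
    s = make_schedule(seed)
    df = s.trials
    assert len(df) == 48
    assert (df.groupby("posture").size() == 24).all()
    counts = df.groupby(["condition", "posture"]).size()
    assert (counts == 6).all() and len(counts) == 8
    assert set(df.loc[df.condition == "tactile_only", "block"]) <= {3, 6}
    assert (df.loc[df.block <= 3, "posture"] == "uncrossed").all()
    assert _scan_max_run(df) <= 2
    check_schedule(s)


def test_schedule_deterministic():
    assert make_schedule(0).trials.equals(make_schedule(0).trials)
    assert not make_schedule(0).trials.equals(make_schedule(1).trials)


def test_read_write_roundtrip(tiny_trials, tmp_path):
    path = tmp_path / "trials.csv"
    write_trials(tiny_trials, path)
    back = read_trials(path)
    assert len(back) == 4
    pd.testing.assert_frame_equal(back, tiny_trials, check_dtype=False)


def test_roundtrip_simulated(default_trials, tmp_path):
    path = tmp_path / "sim.csv"
    write_trials(default_trials, path)
    back = read_trials(path)
    pd.testing.assert_frame_equal(back, default_trials, check_dtype=False)


def test_read_rejects_bad_schema_and_invariants(tiny_trials, tmp_path):
    bad = tiny_trials.copy()
    bad.loc[1, "auditory_side"] = "left"  # tactile_only must have auditory none
    with pytest.raises(ValidationError, match="tactile_only"):
        validate_trials(bad)

    path = tmp_path / "missing.csv"
    tiny_trials.drop(columns=["rt_s"]).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="rt_s"):
        read_trials(path)


def test_filter_null_and_cutoff(tiny_trials):
    sim = simulate_dataset(SimConfig(seed=11, n_per_group=2))
    kept, acc = filter_trials(sim)
    n_null = int((sim.response_modality == "null").sum())
    assert len(kept) == len(sim) - n_null
    assert acc["n_null"].sum() == n_null
    # strict cutoff: exactly 4.0 s is retained
    df = tiny_trials[tiny_trials.response_modality != "null"].copy()
    df["rt_s"] = [3.9, 4.0, 4.1]
    kept, _ = filter_trials(df, rt_cutoff_s=4.0)
    assert sorted(kept["rt_s"]) == [3.9, 4.0]
    # idempotence
    again, _ = filter_trials(kept, rt_cutoff_s=4.0)
    pd.testing.assert_frame_equal(again, kept)


def test_reconcile_identical_streams(default_trials):
    pairs = simulate_raters(default_trials, SimConfig(seed=7, rater_disagree=0.0, rater_rt_sd=0.0))
    reconciled, summary = reconcile_ratings(pairs)
    assert summary.n_disagreed == 0
    assert summary.n_agreed == len(default_trials)
    nonnull = default_trials.response_modality != "null"
    assert np.allclose(
        reconciled.loc[nonnull, "rt_s"],
        np.round(default_trials.loc[nonnull, "rt_s"] * 25) / 25,
    )


def test_reconcile_disagreement_excluded(tiny_trials):
    pairs = simulate_raters(tiny_trials, SimConfig(seed=0, rater_disagree=0.0, rater_rt_sd=0.0))
    pairs.loc[0, "response_side_r2"] = "right"  # rater 2 saw the other side
    reconciled, summary = reconcile_ratings(pairs)
    assert summary.n_disagreed == 1
    assert reconciled.loc[0, "response_modality"] == "null"
    assert pd.isna(reconciled.loc[0, "rt_s"])


def test_reconcile_counts_match_direct_comparison_oracle(default_trials):
    cfg = SimConfig(seed=7, rater_disagree=0.1)
    pairs = simulate_raters(default_trials.head(100), cfg)
    _, summary = reconcile_ratings(pairs)
    # independent per-trial comparison
    direct = sum(
        (a != b) or (m1 != m2)
        for a, b, m1, m2 in zip(
            pairs.response_side_r1, pairs.response_side_r2,
            pairs.response_modality_r1, pairs.response_modality_r2,
        )
    )
    assert summary.n_disagreed == direct
    # reconciliation never invents responses
    n1 = int((pairs.response_side_r1 != "null").sum())
    n2 = int((pairs.response_side_r2 != "null").sum())
    assert summary.n_agreed - summary.counts["both_null"] <= min(n1, n2)


def test_response_outcome_coding(tiny_trials):
    df = tiny_trials[tiny_trials.response_modality != "null"]
    out = response_outcome(df)
    # rows: auditory left/resp left; tactile right/resp right; congruent left/resp left
    assert out.tolist() == [1, 1, 1]
    flipped = df.copy()
    flipped["response_side"] = ["right", "left", "right"]
    assert response_outcome(flipped).tolist() == [0, 0, 0]
    # incongruent: 1 = toward the auditory stimulus
    incong = tiny_trials.iloc[[3]].copy()
    incong["response_modality"] = "arm_hand"
    incong["response_side"] = "right"  # auditory side
    incong["rt_s"] = 1.0
    assert response_outcome(incong).tolist() == [1]
    incong["response_side"] = "left"
    assert response_outcome(incong).tolist() == [0]
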