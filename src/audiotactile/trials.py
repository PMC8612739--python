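"""Trial-level data model, session schedules, rater reconciliation and filtering.

The unit of observation is one stimulus presentation to an infant's hands
(a *trial*): a design cell (block, posture, condition, stimulated side(s))
plus the coded first orienting response (modality, side, latency).  Trials
live in a pandas DataFrame with the fixed column schema in :data:`SCHEMA`;
all downstream modules consume that frame.

A session presents at most 48 trials in 6 blocks: blocks 1-3 with the hands
uncrossed, blocks 4-6 crossed.  Auditory-only, audiotactile-congruent and
audiotactile-incongruent trials are interleaved in blocks 1, 2, 4 and 5;
tactile-only trials fill blocks 3 and 6.  Each condition occurs 12 times
(6 per posture) and the same hand never receives the same sensory cue on
more than 2 consecutive trials.  :func:`make_schedule` regenerates such an
order by constrained pseudorandomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA",
    "GROUPS",
    "POSTURES",
    "CONDITIONS",
    "SIDES",
    "MODALITIES",
    "FRAME_S",
    "SessionSchedule",
    "SchemaError",
    "ValidationError",
    "make_schedule",
    "read_trials",
    "write_trials",
    "validate_trials",
    "reconcile_ratings",
    "filter_trials",
    "response_outcome",
]

#: canonical column order of a trial table
SCHEMA = [
    "participant_id",
    "group",
    "age_months",
    "block",
    "posture",
    "condition",
    "tactile_side",
    "auditory_side",
    "response_modality",
    "response_side",
    "rt_s",
    "valid",
]

GROUPS = ["S", "SVI"]
POSTURES = ["uncrossed", "crossed"]
CONDITIONS = ["tactile_only", "auditory_only", "at_congruent", "at_incongruent"]
SIDES = ["left", "right", "none"]
MODALITIES = ["arm_hand", "eye_head", "both", "null"]

#: video frame duration (coding video runs at 25 frames per second)
FRAME_S = 1.0 / 25.0

#: response window after stimulus offset, seconds
RESPONSE_WINDOW_S = 8.0

_SCHEDULE_COLS = ["block", "posture", "condition", "tactile_side", "auditory_side"]


class SchemaError(ValueError):
    """A trial table does not carry the documented columns."""


class ValidationError(ValueError):
    """Rows of a trial table violate the trial invariants."""

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        super().__init__("invalid trial rows:\n" + "\n".join(self.messages))


class ScheduleError(RuntimeError):
    """Constrained schedule sampling did not converge (should not occur)."""


@dataclass
class SessionSchedule:
    """Pseudorandom stimulus order for one 48-trial session."""

    trials: pd.DataFrame  # columns: block, posture, condition, tactile_side, auditory_side
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return self.trials.copy()


def _stimulated_keys(cond: str, t_side: str, a_side: str) -> frozenset:
    """(hand, cue) pairs a trial stimulates, for the consecutive-run constraint."""
    keys = set()
    if t_side != "none":
        keys.add((t_side, "tactile"))
    if a_side != "none":
        keys.add((a_side, "auditory"))
    return frozenset(keys)


def max_same_cue_run(rows: list[tuple]) -> int:
    """Longest run of consecutive trials stimulating the same hand with the same cue.

    ``rows`` are (block, posture, condition, tactile_side, auditory_side) tuples.
    """
    best = 0
    run: dict = {}
    for row in rows:
        keys = _stimulated_keys(row[2], row[3], row[4])
        run = {k: run.get(k, 0) + 1 for k in keys}
        if run:
            best = max(best, max(run.values()))
    return best


def _mixed_block_pool(posture: str) -> list[tuple]:
    """18 interleaved trials of one posture: 3 L + 3 R per non-tactile condition."""
    pool = []
    for side in ("left", "right"):
        pool += [("auditory_only", "none", side)] * 3
        pool += [("at_congruent", side, side)] * 3
    pool += [("at_incongruent", "left", "right")] * 3
    pool += [("at_incongruent", "right", "left")] * 3
    return [(posture, c, t, a) for (c, t, a) in pool]


def make_schedule(seed: int, max_attempts: int = 10_000) -> SessionSchedule:
    """Generate one full 48-trial session schedule by rejection sampling.

    Blocks are filled one at a time; a candidate block order is rejected if
    the schedule built so far would stimulate the same hand with the same
    sensory cue on more than 2 consecutive trials (checked across block
    boundaries).  Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    for _ in range(50):  # whole-schedule restarts; essentially never needed
        rows: list[tuple] = []
        ok = True
        for block in range(1, 7):
            posture = "uncrossed" if block <= 3 else "crossed"
            if block in (3, 6):
                pool = [(posture, "tactile_only", s, "none") for s in ("left", "right") for _ in range(3)]
            elif block in (1, 4):
                # blocks 1+2 (resp. 4+5) share one shuffled 18-trial pool
                pending = _mixed_block_pool(posture)
            if block in (3, 6):
                cand_pool = pool
                take = 6
            else:
                cand_pool = pending
                take = 9
            placed = None
            for _ in range(max_attempts):
                idx = rng.permutation(len(cand_pool))
                cand = [cand_pool[i] for i in idx[:take]]
                cand_rows = [(block, p, c, t, a) for (p, c, t, a) in cand]
                if max_same_cue_run(rows + cand_rows) <= 2:
                    placed = cand_rows
                    remaining = [cand_pool[i] for i in idx[take:]]
                    break
            if placed is None:
                ok = False
                break
            rows += placed
            if block in (1, 4):
                pending = remaining
        if ok:
            df = pd.DataFrame(rows, columns=_SCHEDULE_COLS)
            return SessionSchedule(trials=df, seed=seed)
    raise ScheduleError(f"schedule constraints not satisfied within bounds (seed={seed})")


def check_schedule(schedule: SessionSchedule) -> None:
    """Raise AssertionError unless all schedule invariants hold."""
    df = schedule.trials
    assert len(df) == 48, "schedule must have 48 trials"
    assert sorted(df["block"].unique()) == [1, 2, 3, 4, 5, 6]
    assert (df.loc[df["block"] <= 3, "posture"] == "uncrossed").all()
    assert (df.loc[df["block"] >= 4, "posture"] == "crossed").all()
    tact_blocks = df.loc[df["condition"] == "tactile_only", "block"].unique()
    assert set(tact_blocks) <= {3, 6}, "tactile-only trials only in blocks 3 and 6"
    counts = df.groupby(["condition", "posture"], observed=True).size()
    for cond in CONDITIONS:
        for post in POSTURES:
            assert counts.get((cond, post), 0) == 6, f"{cond}/{post} must occur 6 times"
    rows = list(df[_SCHEDULE_COLS].itertuples(index=False, name=None))
    assert max_same_cue_run(rows) <= 2, "same hand+cue on >2 consecutive trials"


# ---------------------------------------------------------------------------
# trial-table I/O and validation


def _row_errors(row: pd.Series, i) -> list[str]:
    errs = []
    c, t, a = row["condition"], row["tactile_side"], row["auditory_side"]
    if row["group"] not in GROUPS:
        errs.append(f"row {i}: unknown group {row['group']!r}")
    if row["posture"] not in POSTURES:
        errs.append(f"row {i}: unknown posture {row['posture']!r}")
    if c not in CONDITIONS:
        errs.append(f"row {i}: unknown condition {c!r}")
        return errs
    if not (1 <= int(row["block"]) <= 6):
        errs.append(f"row {i}: block {row['block']} outside 1-6")
    if int(row["age_months"]) < 0:
        errs.append(f"row {i}: negative age")
    if c == "tactile_only" and not (t in ("left", "right") and a == "none"):
        errs.append(f"row {i}: tactile_only requires tactile side and auditory none")
    if c == "auditory_only" and not (a in ("left", "right") and t == "none"):
        errs.append(f"row {i}: auditory_only requires auditory side and tactile none")
    if c == "at_congruent" and not (t == a and t in ("left", "right")):
        errs.append(f"row {i}: at_congruent requires equal non-none sides")
    if c == "at_incongruent" and not (
        t in ("left", "right") and a in ("left", "right") and t != a
    ):
        errs.append(f"row {i}: at_incongruent requires different non-none sides")
    mod, side, rt = row["response_modality"], row["response_side"], row["rt_s"]
    is_null = mod == "null"
    if is_null != (side == "null") or is_null != pd.isna(rt):
        errs.append(f"row {i}: null response requires modality=side=null and absent rt")
    if mod not in MODALITIES:
        errs.append(f"row {i}: unknown response modality {mod!r}")
    if not is_null and side not in ("left", "right"):
        errs.append(f"row {i}: unknown response side {side!r}")
    if not pd.isna(rt) and not (0.0 < rt <= RESPONSE_WINDOW_S):
        errs.append(f"row {i}: rt_s {rt} outside (0, {RESPONSE_WINDOW_S}]")
    return errs


def validate_trials(trials: pd.DataFrame) -> None:
    """Check the schema and every per-row invariant; raise listing offenders."""
    missing = [c for c in SCHEMA if c not in trials.columns]
    extra = [c for c in trials.columns if c not in SCHEMA]
    if missing or extra:
        raise SchemaError(f"missing columns {missing}, unexpected columns {extra}")
    errors = []
    for i, row in trials.iterrows():
        errors += _row_errors(row, i)
    if errors:
        raise ValidationError(errors)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table from delimited text (comma-separated)."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "group": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in SCHEMA if c not in df.columns]
    extra = [c for c in df.columns if c not in SCHEMA]
    if missing or extra:
        raise SchemaError(f"missing columns {missing}, unexpected columns {extra}")
    df = df[SCHEMA]
    df["rt_s"] = pd.to_numeric(df["rt_s"], errors="coerce")
    df["valid"] = df["valid"].astype(bool)
    for col in ("age_months", "block"):
        df[col] = df[col].astype(int)
    validate_trials(df)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 comma-delimited text (empty string = absent RT)."""
    trials[SCHEMA].to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# dual-rater reconciliation


@dataclass
class ReconcileSummary:
    n_trials: int
    n_agreed: int
    n_disagreed: int
    n_null: int  # trials null after reconciliation (both-null or excluded)
    counts: dict = field(default_factory=dict)


def reconcile_ratings(pairs: pd.DataFrame) -> tuple[pd.DataFrame, ReconcileSummary]:
    """Merge two raters' codes for the same trial set into one analysis table.

    ``pairs`` carries the design columns plus ``response_modality_r1`` /
    ``_r2``, ``response_side_r1`` / ``_r2`` and ``rt_s_r1`` / ``_r2``.  Trials
    on which the raters still disagree about the side or modality of the
    response are designated null and excluded from analysis.  Where the
    raters agree, the reconciled RT is the mean of the two ratings quantized
    to the 1/25 s video frame.
    """
    rater_cols = [f"{c}_{r}" for c in ("response_modality", "response_side", "rt_s") for r in ("r1", "r2")]
    missing = [c for c in rater_cols if c not in pairs.columns]
    if missing:
        raise SchemaError(f"rating table lacks rater columns {missing}")

    out = pairs.copy()
    agree = (out["response_side_r1"] == out["response_side_r2"]) & (
        out["response_modality_r1"] == out["response_modality_r2"]
    )
    both_null = (out["response_modality_r1"] == "null") & (out["response_modality_r2"] == "null")

    mod = np.where(agree, out["response_modality_r1"], "null")
    side = np.where(agree, out["response_side_r1"], "null")
    rt = np.where(
        agree & ~both_null,
        np.round((out["rt_s_r1"].to_numpy(float) + out["rt_s_r2"].to_numpy(float)) / 2.0 / FRAME_S) * FRAME_S,
        np.nan,
    )
    out["response_modality"] = mod
    out["response_side"] = side
    out["rt_s"] = rt
    out["rater_agreed"] = agree.to_numpy()
    reconciled = out.drop(columns=rater_cols)

    n_dis = int((~agree).sum())
    summary = ReconcileSummary(
        n_trials=len(out),
        n_agreed=int(agree.sum()),
        n_disagreed=n_dis,
        n_null=int(((mod == "null")).sum()),
        counts={"both_null": int(both_null.sum())},
    )
    return reconciled, summary


# ---------------------------------------------------------------------------
# filtering


def filter_trials(
    trials: pd.DataFrame, rt_cutoff_s: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop null-response trials and (optionally) slow responses.

    The RT cutoff is strict: responses *longer than* the cutoff are excluded,
    a response exactly at the cutoff is retained.  Returns the retained
    trials and a per-group accounting frame with columns ``n_in``, ``n_null``,
    ``n_slow``, ``n_out``.  Applying the same filter twice is a no-op.
    """
    null_mask = trials["response_modality"] == "null"
    slow_mask = pd.Series(False, index=trials.index)
    if rt_cutoff_s is not None:
        slow_mask = trials["rt_s"] > rt_cutoff_s
    keep = ~(null_mask | slow_mask)

    acc = pd.DataFrame(
        {
            "n_in": trials.groupby("group", observed=True).size(),
            "n_null": trials[null_mask].groupby("group", observed=True).size(),
            "n_slow": trials[slow_mask].groupby("group", observed=True).size(),
            "n_out": trials[keep].groupby("group", observed=True).size(),
        }
    ).fillna(0).astype(int)
    return trials[keep].copy(), acc


def response_outcome(trials: pd.DataFrame) -> pd.Series:
    """Binary orienting outcome: 1 = response toward the stimulated limb.

    For unisensory trials the stimulated limb is the cued side; for
    audiotactile-congruent trials both cues share a side.  For
    audiotactile-incongruent trials "toward the stimulated limb" is undefined
    (both are stimulated); there the code is 1 when the response was with or
    toward the *auditory* stimulus location.
    """
    if (trials["response_modality"] == "null").any():
        raise ValueError("response_outcome requires null trials to be filtered out")
    stim_side = trials["tactile_side"].where(trials["tactile_side"] != "none", trials["auditory_side"])
    incong = trials["condition"] == "at_incongruent"
    target = stim_side.where(~incong, trials["auditory_side"])
    return (trials["response_side"] == target).astype(int)
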