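"""Race-model redundancy-gain analysis of orienting latencies.

If auditory and tactile channels race independently, the bimodal RT
distribution can be no faster than the bound

    G(t) = min(1, F_A(t) + F_T(t)),

the sum of the unisensory empirical CDFs (Miller's inequality).  The
analysis works in the RT (quantile) domain: for each participant and
posture the nine deciles (10-90 %) of the audiotactile CDF are compared
with the deciles of the race bound, and the per-decile *gain*

    gain(q) = RT_bound(q) − RT_AT(q)

is positive when bimodal responding beats the bound (a race-model
violation, i.e. evidence of multisensory integration).  Gains are computed
within participant first, then aggregated: per group and decile a
one-sample one-tailed t test against zero (Bonferroni-corrected for the 9
deciles), and per decile a two-tailed Welch t test between groups
(same correction).

Quantiles use the type-1 (inverse step-CDF) estimator throughout, so the
step-function bound and the empirical CDFs are inverted consistently; a
linearly interpolated estimator is available behind ``method="linear"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DECILES",
    "QuantileProfile",
    "RaceGainTable",
    "participant_quantiles",
    "race_bound_quantiles",
    "redundancy_gain",
]

#: the nine probed deciles of each CDF
DECILES = np.round(np.arange(0.1, 0.91, 0.1), 10)


class EmptyCellError(ValueError):
    """A participant has no valid RTs in a required condition cell."""


@dataclass
class QuantileProfile:
    participant_id: str
    condition: str  # 'A', 'T', 'AT' or 'race_bound'
    probs: np.ndarray
    rt_at_prob: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, float)
        self.rt_at_prob = np.asarray(self.rt_at_prob, float)
        if np.any(np.diff(self.rt_at_prob) < -1e-12):
            raise ValueError("quantiles must be non-decreasing in probability")


@dataclass
class RaceGainTable:
    gains: pd.DataFrame       # per group x posture x decile: mean, se, t, df, p, p_adj
    group_tests: pd.DataFrame  # per posture x decile: Welch t, df, p, p_adj
    per_participant: pd.DataFrame
    dropped: list = field(default_factory=list)


def _type1_quantile(sorted_rts: np.ndarray, q: float) -> float:
    """Smallest observed value whose empirical CDF reaches q."""
    n = len(sorted_rts)
    k = int(np.ceil(q * n - 1e-12))  # F(x_(k)) = k/n >= q
    return float(sorted_rts[max(k - 1, 0)])


def participant_quantiles(
    rts, probs=DECILES, participant_id: str = "", condition: str = "",
    method: str = "type1",
) -> QuantileProfile:
    """Empirical-CDF quantiles of one participant's RTs in one cell."""
    x = np.sort(np.asarray(rts, float))
    if len(x) == 0:
        raise EmptyCellError(f"no RTs for participant {participant_id!r} cell {condition!r}")
    probs = np.asarray(probs, float)
    if np.any((probs <= 0) | (probs >= 1)) or np.any(np.diff(probs) <= 0):
        raise ValueError("probs must be strictly increasing within (0, 1)")
    if method == "type1":
        qs = np.array([_type1_quantile(x, q) for q in probs])
    elif method == "linear":
        qs = np.quantile(x, probs)
    else:
        raise ValueError(f"unknown quantile method {method!r}")
    return QuantileProfile(participant_id, condition or "A", probs, qs)


def race_bound_quantiles(
    rt_A, rt_T, probs=DECILES, participant_id: str = ""
) -> QuantileProfile:
    """Quantiles of the race bound G(t) = min(1, F_A(t) + F_T(t)).

    The bound is a step function on the pooled support; the quantile at q is
    the smallest pooled RT at which G reaches q (type-1 inversion).
    """
    a = np.sort(np.asarray(rt_A, float))
    t = np.sort(np.asarray(rt_T, float))
    if len(a) == 0 or len(t) == 0:
        raise EmptyCellError(f"empty unisensory cell for participant {participant_id!r}")
    support = np.unique(np.concatenate([a, t]))
    FA = np.searchsorted(a, support, side="right") / len(a)
    FT = np.searchsorted(t, support, side="right") / len(t)
    G = np.minimum(1.0, FA + FT)
    probs = np.asarray(probs, float)
    qs = np.empty(len(probs))
    for i, q in enumerate(probs):
        j = np.searchsorted(G, q - 1e-12, side="left")
        qs[i] = support[min(j, len(support) - 1)]
    return QuantileProfile(participant_id, "race_bound", probs, qs)


def redundancy_gain(
    trials: pd.DataFrame,
    probs=DECILES,
    alpha: float = 0.05,
    rt_col: str = "rt_s",
) -> RaceGainTable:
    """Per-decile redundancy gains from a filtered trial table.

    Expects non-null trials; uses RTs of responses toward the stimulated
    limb in the auditory-only (A), tactile-only (T) and audiotactile-
    congruent (AT) conditions, separately per posture.  Participants missing
    any of the three cells in a posture are dropped listwise from that
    posture (logged in ``dropped``).
    """
    from .trials import response_outcome

    df = trials[trials["condition"].isin(["auditory_only", "tactile_only", "at_congruent"])]
    df = df[df["response_modality"] != "null"]
    df = df[response_outcome(df) == 1]

    cond_map = {"auditory_only": "A", "tactile_only": "T", "at_congruent": "AT"}
    probs = np.asarray(probs, float)
    rows = []
    dropped = []
    for (posture, pid), sub in df.groupby(["posture", "participant_id"], observed=True):
        cells = {
            cond_map[c]: sub.loc[sub["condition"] == c, rt_col].dropna().to_numpy()
            for c in cond_map
        }
        if any(len(v) == 0 for v in cells.values()):
            dropped.append((pid, posture))
            continue
        group = sub["group"].iloc[0]
        at = participant_quantiles(cells["AT"], probs, pid, "AT")
        bound = race_bound_quantiles(cells["A"], cells["T"], probs, pid)
        for q, g in zip(probs, bound.rt_at_prob - at.rt_at_prob):
            rows.append((group, posture, pid, q, g))
    per = pd.DataFrame(rows, columns=["group", "posture", "participant_id", "decile", "gain_s"])

    gain_rows, cmp_rows = [], []
    for (group, posture, q), sub in per.groupby(["group", "posture", "decile"], observed=True):
        g = sub["gain_s"].to_numpy()
        n = len(g)
        if n < 2:
            continue
        se = g.std(ddof=1) / np.sqrt(n)
        t_res = stats.ttest_1samp(g, 0.0, alternative="greater")
        p_adj = min(1.0, t_res.pvalue * len(probs))
        gain_rows.append(
            (group, posture, q, g.mean(), se, float(t_res.statistic), n - 1,
             float(t_res.pvalue), p_adj, p_adj < alpha)
        )
    gains = pd.DataFrame(
        gain_rows,
        columns=["group", "posture", "decile", "mean_gain_s", "se", "t", "df",
                 "p", "p_adj", "significant"],
    )

    for (posture, q), sub in per.groupby(["posture", "decile"], observed=True):
        by_group = {g: s["gain_s"].to_numpy() for g, s in sub.groupby("group", observed=True)}
        if len(by_group) != 2 or any(len(v) < 2 for v in by_group.values()):
            continue
        (g1, x1), (g2, x2) = sorted(by_group.items())
        w = stats.ttest_ind(x1, x2, equal_var=False)
        df_w = _welch_df(x1, x2)
        p_adj = min(1.0, w.pvalue * len(probs))
        cmp_rows.append(
            (posture, q, f"{g1} - {g2}", x1.mean() - x2.mean(), float(w.statistic),
             df_w, float(w.pvalue), p_adj, p_adj < alpha)
        )
    group_tests = pd.DataFrame(
        cmp_rows,
        columns=["posture", "decile", "comparison", "mean_diff_s", "t", "df",
                 "p", "p_adj", "significant"],
    )
    return RaceGainTable(gains=gains, group_tests=group_tests, per_participant=per,
                         dropped=dropped)


def _welch_df(x1: np.ndarray, x2: np.ndarray) -> float:
    """Welch-Satterthwaite fractional degrees of freedom."""
    v1, v2 = x1.var(ddof=1) / len(x1), x2.var(ddof=1) / len(x2)
    if v1 + v2 == 0:
        return float(len(x1) + len(x2) - 2)
    return float((v1 + v2) ** 2 / (v1**2 / (len(x1) - 1) + v2**2 / (len(x2) - 1)))
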