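"""Synthetic orienting-response datasets with the structure the analysis assumes.

The generator emulates a two-group infant study (sighted ``S`` vs severely
visually impaired ``SVI``, 10 infants per group by default) in which each
participant receives a constrained pseudorandom 48-trial session.  Two
latent components drive the simulated behaviour:

* **Orienting direction** — a Bernoulli draw from a logistic model whose
  linear predictor combines fixed effects (group, posture, condition, age)
  with a participant-level random intercept ``u ~ N(0, sigma_u^2)``.  This
  is the generative twin of the random-intercept logistic GLMM fitted
  downstream.
* **Response latency** — a two-channel race.  Each sensory channel (auditory,
  tactile) draws a shifted-lognormal finishing time; a unisensory trial
  returns its channel's draw, a congruent bimodal trial returns the minimum
  of both draws minus a coactivation term ``violation_v`` (0 = the race-model
  inequality holds; > 0 produces violations at the deciles the downstream
  race analysis probes).  On incongruent trials the responded-to stimulus is
  tactile with probability ``tactile_pref`` and the latency is the winning
  channel's draw.

Null responses (no codable orienting movement) are inserted at rate
``p_null`` (~5 %, the rate the study design anticipates).  A second
simulated rater supports the reliability analyses: rater 1 is ground truth,
rater 2 flips the coded side at a configurable rate and jitters RTs with
frame-quantized Gaussian noise, mimicking coding from 25 fps video.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .trials import FRAME_S, SCHEMA, make_schedule

__all__ = ["SimConfig", "simulate_dataset", "simulate_raters"]

_MIN_RT_S = 0.08  # floor for coactivation-shifted RTs (2 video frames)


def _default_beta() -> dict[str, float]:
    # log-odds of orienting toward the stimulated limb; reference coding of the
    # generator is: group_svi, posture_crossed in {0,1}, age centered (months)
    return {
        "intercept": 1.0,
        "group_svi": -0.2,
        "posture_crossed": -0.8,
        "group_svi:posture_crossed": 0.9,
        "age_c": 0.0,
    }


def _default_channels() -> dict[str, dict[str, dict[str, float]]]:
    # shifted-lognormal finishing times per group and channel, seconds;
    # medians ~1.6-1.8 s, right tails into the 3-4 s range typical of infant
    # orienting latencies
    ch = {
        "auditory": {"t0": 0.3, "mu": 0.30, "sigma": 0.45},
        "tactile": {"t0": 0.3, "mu": 0.40, "sigma": 0.45},
    }
    return {"S": {k: dict(v) for k, v in ch.items()}, "SVI": {k: dict(v) for k, v in ch.items()}}


@dataclass
class SimConfig:
    """Parameters of the simulated study (defaults = the stated design)."""

    n_per_group: int = 10
    seed: int = 0
    age_range_months: tuple[int, int] = (5, 35)
    beta: dict = field(default_factory=_default_beta)
    sigma_u: float = 0.5
    channel_params: dict = field(default_factory=_default_channels)
    violation_v: float = 0.15
    tactile_pref: float = 0.5
    p_null: float = 0.05
    rater_disagree: float = 0.03
    rater_rt_sd: float = 0.04
    # session attrition: trials completed before the infant disengages, drawn
    # latent-normal and clipped to [10, 48]; the defaults yield ~45.5 completed
    # trials on average (SD ~3), the completion level the study design reports
    completed_mean: float = 46.0
    completed_sd: float = 3.5

    def validate(self) -> None:
        probs = {"tactile_pref": self.tactile_pref, "p_null": self.p_null,
                 "rater_disagree": self.rater_disagree}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if self.violation_v < 0:
            raise ValueError("violation_v must be >= 0")
        if self.completed_sd < 0 or self.rater_rt_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for grp, chans in self.channel_params.items():
            for ch, p in chans.items():
                if p["sigma"] <= 0:
                    raise ValueError(f"channel sigma must be > 0 ({grp}/{ch})")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "age_range_months" in raw:
            raw["age_range_months"] = tuple(raw["age_range_months"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["age_range_months"] = list(self.age_range_months)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _linear_predictor(beta: dict, group: str, posture: str, condition: str, age_c: float) -> float:
    g = 1.0 if group == "SVI" else 0.0
    p = 1.0 if posture == "crossed" else 0.0
    eta = beta.get("intercept", 0.0)
    eta += beta.get("group_svi", 0.0) * g
    eta += beta.get("posture_crossed", 0.0) * p
    eta += beta.get("group_svi:posture_crossed", 0.0) * g * p
    eta += beta.get("age_c", 0.0) * age_c
    eta += beta.get(f"condition_{condition}", 0.0)
    return eta


def _channel_draw(rng: np.random.Generator, params: dict) -> float:
    return params["t0"] + float(np.exp(rng.normal(params["mu"], params["sigma"])))


def simulate_dataset(config: SimConfig) -> pd.DataFrame:
    """Simulate a full two-group study; returns a schema-valid trial table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range_months
    rows = []
    pid = 0
    for group in ("S", "SVI"):
        chans = config.channel_params[group]
        for _ in range(config.n_per_group):
            pid += 1
            participant = f"{group.lower()}{pid:02d}"
            age = int(rng.integers(lo, hi + 1))
            age_c = age - (lo + hi) / 2.0
            u = rng.normal(0.0, config.sigma_u) if config.sigma_u > 0 else 0.0
            sched = make_schedule(int(rng.integers(0, 2**31 - 1)))
            n_completed = int(np.clip(round(rng.normal(config.completed_mean, config.completed_sd)), 10, 48))
            for s in sched.trials.head(n_completed).itertuples(index=False):
                cond = s.condition
                if rng.random() < config.p_null:
                    mod, side, rt = "null", "null", np.nan
                else:
                    eta = _linear_predictor(config.beta, group, s.posture, cond, age_c) + u
                    toward = rng.random() < 1.0 / (1.0 + np.exp(-eta))
                    if cond == "tactile_only":
                        rt = _channel_draw(rng, chans["tactile"])
                        stim = s.tactile_side
                        side = stim if toward else _other(stim)
                    elif cond == "auditory_only":
                        rt = _channel_draw(rng, chans["auditory"])
                        stim = s.auditory_side
                        side = stim if toward else _other(stim)
                    elif cond == "at_congruent":
                        rt = min(_channel_draw(rng, chans["auditory"]),
                                 _channel_draw(rng, chans["tactile"]))
                        rt = max(rt - config.violation_v, _MIN_RT_S)
                        stim = s.tactile_side
                        side = stim if toward else _other(stim)
                    else:  # at_incongruent: 'toward' means toward the auditory side
                        if rng.random() < config.tactile_pref:
                            rt = _channel_draw(rng, chans["tactile"])
                            side = s.tactile_side
                        else:
                            rt = _channel_draw(rng, chans["auditory"])
                            side = s.auditory_side
                    rt = min(rt, 8.0)
                    mod = str(rng.choice(["arm_hand", "eye_head", "both"], p=[0.64, 0.28, 0.08]))
                rows.append(
                    (participant, group, age, int(s.block), s.posture, cond,
                     s.tactile_side, s.auditory_side, mod, side,
                     round(rt, 6) if np.isfinite(rt) else np.nan, True)
                )
    return pd.DataFrame(rows, columns=SCHEMA)


def _other(side: str) -> str:
    return "right" if side == "left" else "left"


def simulate_raters(trials: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Emit a dual-rater coding table for ``trials``.

    Rater 1 reproduces the true codes.  Rater 2 flips the response side with
    probability ``rater_disagree`` and reports the RT plus Gaussian jitter
    (SD ``rater_rt_sd`` seconds) quantized to the 1/25 s video frame.
    """
    if len(trials) == 0:
        raise ValueError("simulate_raters requires a non-empty trial table")
    rng = np.random.default_rng(config.seed + 1)
    out = trials.drop(columns=["response_modality", "response_side", "rt_s"]).copy()
    out["response_modality_r1"] = trials["response_modality"].to_numpy()
    out["response_side_r1"] = trials["response_side"].to_numpy()
    out["rt_s_r1"] = trials["rt_s"].to_numpy()

    side2 = trials["response_side"].to_numpy().copy()
    nonnull = side2 != "null"
    flip = (rng.random(len(side2)) < config.rater_disagree) & nonnull
    side2[flip] = ["right" if s == "left" else "left" for s in side2[flip]]
    rt2 = trials["rt_s"].to_numpy(float) + rng.normal(0.0, config.rater_rt_sd, len(side2))
    rt2 = np.round(rt2 / FRAME_S) * FRAME_S
    rt2 = np.clip(rt2, FRAME_S, 8.0)
    rt2[~nonnull] = np.nan
    out["response_modality_r2"] = trials["response_modality"].to_numpy()
    out["response_side_r2"] = side2
    out["rt_s_r2"] = rt2
    return out
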