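"""End-to-end orchestration: data in, reconciled/filtered trials, models, report.

The pipeline mirrors the study's analysis plan.  Orienting responses feed
four mixed-model analyses (auditory localization, tactile localization,
multisensory gain, crossmodal conflict), each pairing a logistic GLMM of
response direction with an LMM of response latency, evaluated by Type III
Wald chi-square tests and followed up with Bonferroni-corrected EMM
contrasts.  The race-model analysis quantifies redundancy gains per decile,
and the reliability stage summarizes dual-rater agreement.  Every filtering
step is logged with per-group trial counts so the trial-accounting
narrative stays auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import yaml

from . import race as race_mod
from . import reliability as rel_mod
from .design import ModelSpec
from .mixed_models import emm_contrasts, fit_glmm_logit, fit_lmm, wald_type3
from .simulate import SimConfig, simulate_dataset, simulate_raters
from .trials import filter_trials, read_trials, reconcile_ratings, response_outcome

log = logging.getLogger("audiotactile")

__all__ = ["AnalysisConfig", "Report", "run_pipeline", "trial_accounting"]

ANALYSES = [
    "auditory_localization",
    "tactile_localization",
    "multisensory_gain",
    "crossmodal_conflict",
    "race_model",
    "reliability",
]

#: conditions entering each mixed-model analysis (condition order = factor order)
_MODEL_CONDITIONS = {
    "auditory_localization": ["auditory_only"],
    "tactile_localization": ["tactile_only"],
    "multisensory_gain": ["tactile_only", "auditory_only", "at_congruent"],
    "crossmodal_conflict": ["tactile_only", "auditory_only", "at_incongruent"],
}


@dataclass
class AnalysisConfig:
    """What to run and on what data."""

    input_path: str | None = None      # trial table on disk; None = simulate
    sim: SimConfig | None = None       # simulation config when input_path is None
    analyses: list[str] = field(default_factory=lambda: list(ANALYSES))
    rt_cutoff_s: float | None = None   # sensitivity mode: 4.0
    hand_arm_only: bool = False        # tactile-localization sensitivity analysis
    n_quad: int = 1
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        bad = set(self.analyses) - set(ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses {sorted(bad)}")
        if not self.analyses:
            raise ValueError("at least one analysis must be selected")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        return cls(**raw)


@dataclass
class Report:
    wald: dict = field(default_factory=dict)        # analysis -> {glmm, lmm} tables
    contrasts: dict = field(default_factory=dict)
    race: race_mod.RaceGainTable | None = None
    reliability: dict = field(default_factory=dict)
    accounting: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)     # stage -> reason
    config: AnalysisConfig | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, pair in self.wald.items():
            for kind, table in pair.items():
                table.table.to_csv(out / f"wald_{name}_{kind}.tsv", sep="\t")
        for name, pair in self.contrasts.items():
            for kind, em in pair.items():
                em.contrasts.to_csv(out / f"contrasts_{name}_{kind}.tsv", sep="\t", index=False)
        if self.race is not None:
            self.race.gains.to_csv(out / "race_gains.tsv", sep="\t", index=False)
            self.race.group_tests.to_csv(out / "race_group_tests.tsv", sep="\t", index=False)
        summary = {
            "reliability": self.reliability,
            "accounting": self.accounting,
            "skipped": self.skipped,
        }
        (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def _analysis_outcome(trials: pd.DataFrame) -> np.ndarray:
    """Binary outcome: toward stimulated limb; toward auditory on incongruent."""
    return response_outcome(trials).to_numpy()


def _rt_rows(trials: pd.DataFrame) -> pd.DataFrame:
    """Rows entering the latency LMM: responses to the stimulated hand
    (either hand counts on audiotactile-incongruent trials)."""
    incong = trials["condition"] == "at_incongruent"
    toward = response_outcome(trials) == 1
    keep = trials[(incong | toward) & trials["rt_s"].notna()]
    return keep


def run_pipeline(config: AnalysisConfig) -> Report:
    """Execute the selected stages in dependency order."""
    report = Report(config=config)

    # --- input ------------------------------------------------------------
    ratings = None
    if config.input_path is not None:
        trials = read_trials(config.input_path)
    else:
        sim = config.sim or SimConfig(seed=config.seed)
        trials = simulate_dataset(sim)
        if "reliability" in config.analyses:
            ratings = simulate_raters(trials, sim)
    log.info("input: %d trials, %d participants", len(trials), trials["participant_id"].nunique())

    # --- reliability + reconciliation -------------------------------------
    if ratings is not None:
        report.reliability = reliability_summary(ratings)
        trials, rec_summary = _reconcile(ratings)
        report.accounting["reconciliation"] = {
            "n_trials": rec_summary.n_trials,
            "n_agreed": rec_summary.n_agreed,
            "n_disagreed_excluded": rec_summary.n_disagreed,
        }
    elif "reliability" in config.analyses:
        report.skipped["reliability"] = "no rater-level codes available in the input"

    # --- accounting & filtering -------------------------------------------
    report.accounting["trials"] = trial_accounting(trials, rt_cutoff_s=4.0)
    analysed, acc = filter_trials(trials, rt_cutoff_s=config.rt_cutoff_s)
    report.accounting["filtering"] = acc
    log.info("filtering: %s", acc.to_dict())

    # --- mixed models -----------------------------------------------------
    for name in config.analyses:
        if name not in _MODEL_CONDITIONS:
            continue
        conds = _MODEL_CONDITIONS[name]
        sub = analysed[analysed["condition"].isin(conds)].copy()
        if name == "tactile_localization" and config.hand_arm_only:
            sub = sub[sub["response_modality"] == "arm_hand"]
        if sub.empty or sub["participant_id"].nunique() < 2:
            report.skipped[name] = "not enough data in the required conditions"
            continue
        factors = ["group", "posture", "age_months"]
        spec_kw = {}
        if len(conds) > 1:
            factors = ["group", "posture", "condition", "age_months"]
            spec_kw["condition_levels"] = conds
        try:
            report.wald[name], report.contrasts[name] = _fit_analysis(
                sub, factors, name, config, **spec_kw
            )
        except Exception as e:  # degenerate cells are report entries, not crashes
            report.skipped[name] = f"model fit failed: {e}"
            log.warning("analysis %s skipped: %s", name, e)

    # --- race model --------------------------------------------------------
    if "race_model" in config.analyses:
        try:
            report.race = race_mod.redundancy_gain(analysed)
        except Exception as e:
            report.skipped["race_model"] = f"race analysis failed: {e}"

    if config.out_dir:
        report.write(config.out_dir)
        _write_manifest(config)
    return report


def _fit_analysis(sub, factors, name, config, **spec_kw):
    glmm_spec = ModelSpec(response="direction_binary", factors=factors, **spec_kw)
    y = _analysis_outcome(sub)
    glmm = fit_glmm_logit(sub, glmm_spec, n_quad=config.n_quad, response=y)

    rt_sub = _rt_rows(sub)
    lmm_spec = ModelSpec(response="rt_seconds", factors=factors, **spec_kw)
    lmm = fit_lmm(rt_sub, lmm_spec)

    wald = {"glmm": wald_type3(glmm), "lmm": wald_type3(lmm)}
    contrasts = {}
    for kind, fit in (("glmm", glmm), ("lmm", lmm)):
        if "condition" in factors:
            # 3-way interaction families: n = 6, 6 and 12 comparisons
            contrasts[kind] = {
                "posture|group*condition": emm_contrasts(
                    fit, compare="posture", by=["group", "condition"], correction_n=6),
                "group|condition*posture": emm_contrasts(
                    fit, compare="group", by=["condition", "posture"], correction_n=6),
                "condition|posture*group": emm_contrasts(
                    fit, compare="condition", by=["posture", "group"], correction_n=12),
            }
        else:
            # 2-way interaction families: n = 2 comparisons each
            contrasts[kind] = {
                "posture|group": emm_contrasts(
                    fit, compare="posture", by=["group"], correction_n=2),
                "group|posture": emm_contrasts(
                    fit, compare="group", by=["posture"], correction_n=2),
            }
    # flatten to one frame per model kind
    flat = {}
    for kind, fam in contrasts.items():
        frames = []
        for famname, em in fam.items():
            f = em.contrasts.copy()
            f.insert(0, "family", famname)
            frames.append(f)
        em0 = next(iter(fam.values()))
        flat[kind] = type(em0)(
            emmeans=pd.concat([e.emmeans for e in fam.values()], ignore_index=True),
            contrasts=pd.concat(frames, ignore_index=True),
            correction_n=0,
        )
    return wald, flat


def _reconcile(ratings: pd.DataFrame):
    reconciled, summary = reconcile_ratings(ratings)
    return reconciled.drop(columns=["rater_agreed"]), summary


def reliability_summary(ratings: pd.DataFrame) -> dict:
    """Kappa (side and modality), weighted kappa, and RT agreement."""
    out = {}
    side_tab = rel_mod.agreement_table(
        ratings["response_side_r1"], ratings["response_side_r2"],
        labels=["left", "right", "null"],
    )
    mods = sorted(set(ratings["response_modality_r1"]) | set(ratings["response_modality_r2"]))
    mod_tab = rel_mod.agreement_table(
        ratings["response_modality_r1"], ratings["response_modality_r2"], labels=mods
    )
    for name, tab in (("side", side_tab), ("modality", mod_tab)):
        k = rel_mod.cohen_kappa(tab)
        kw = rel_mod.weighted_kappa(tab, "linear")
        out[f"kappa_{name}"] = {"kappa": k.kappa, "ci": [k.ci_low, k.ci_high]}
        out[f"weighted_kappa_{name}"] = {"kappa": kw.kappa, "ci": [kw.ci_low, kw.ci_high]}

    both = ratings.dropna(subset=["rt_s_r1", "rt_s_r2"])
    both = both[(both["response_side_r1"] == both["response_side_r2"])]
    if len(both) >= 3:
        rt = rel_mod.rt_agreement(both["rt_s_r1"], both["rt_s_r2"])
        out["rt"] = {
            "pearson_r": rt.pearson_r, "r_ci": list(rt.r_ci),
            "mean_signed_diff_s": rt.mean_signed_diff_s, "diff_ci": list(rt.diff_ci),
            "n": rt.n,
        }
    return out


def trial_accounting(trials: pd.DataFrame, rt_cutoff_s: float = 4.0) -> dict:
    """Per-group completion/contribution statistics with Welch group tests.

    Reports, per group: mean (SD) completed trials per participant, mean (SD)
    contributed (orienting-response) trials, per-modality response
    percentages, and the percentage of contributed responses slower than
    ``rt_cutoff_s``; plus Welch t tests comparing per-participant counts
    between the groups (fractional degrees of freedom).
    """
    per = trials.groupby(["group", "participant_id"], observed=True).agg(
        completed=("valid", "size"),
        contributed=("response_modality", lambda m: int((m != "null").sum())),
    ).reset_index()
    resp = trials[trials["response_modality"] != "null"]

    groups = {}
    for g, sub in per.groupby("group", observed=True):
        r = resp[resp["group"] == g]
        mod_pct = (r["response_modality"].value_counts(normalize=True) * 100).to_dict()
        groups[g] = {
            "n_participants": len(sub),
            "completed_mean": float(sub["completed"].mean()),
            "completed_sd": float(sub["completed"].std(ddof=1)),
            "contributed_mean": float(sub["contributed"].mean()),
            "contributed_sd": float(sub["contributed"].std(ddof=1)),
            "modality_pct": mod_pct,
            "pct_rt_over_cutoff": float((r["rt_s"] > rt_cutoff_s).mean() * 100),
        }

    tests = {}
    glabels = sorted(per["group"].unique())
    if len(glabels) == 2:
        for col in ("completed", "contributed"):
            x1 = per.loc[per["group"] == glabels[0], col].to_numpy(float)
            x2 = per.loc[per["group"] == glabels[1], col].to_numpy(float)
            if len(x1) >= 2 and len(x2) >= 2:
                w = stats.ttest_ind(x1, x2, equal_var=False)
                tests[col] = {
                    "t": float(abs(w.statistic)),
                    "df": race_mod._welch_df(x1, x2),
                    "p": float(w.pvalue),
                    "comparison": f"{glabels[0]} vs {glabels[1]}",
                }
    return {"groups": groups, "welch_tests": tests}


def _write_manifest(config: AnalysisConfig) -> None:
    import audiotactile

    out = Path(config.out_dir)
    manifest = {
        "package": "audiotactile",
        "version": getattr(audiotactile, "__version__", "0"),
        "seed": config.seed,
        "analyses": config.analyses,
        "rt_cutoff_s": config.rt_cutoff_s,
        "hand_arm_only": config.hand_arm_only,
        "input": config.input_path or "simulated",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
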