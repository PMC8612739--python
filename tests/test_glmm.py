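"""The adaptive-quadrature logistic GLMM against closed forms and oracles."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from audiotactile.design import ModelSpec, build_design
from audiotactile.mixed_models import _AgqLoglik, emm_contrasts, fit_glmm_logit

from conftest import logistic_cluster_data


def _two_by_two(n1_success, n1, n0_success, n0):
    """Trial frame with a single binary 'group' predictor and known counts."""
    rows = []
    for i, (succ, tot, grp) in enumerate([(n1_success, n1, "SVI"), (n0_success, n0, "S")]):
        for j in range(tot):
            rows.append((f"{grp}{j}", grp, 12, 1.0 if j < succ else 0.0))
    df = pd.DataFrame(rows, columns=["participant_id", "group", "age_months", "y"])
    return df


def test_two_by_two_closed_form_log_odds_ratio():
    """At sigma_u=0 the group contrast equals the 2x2 log odds ratio log 16."""
    df = _two_by_two(8, 10, 2, 10)
    spec = ModelSpec(response="direction_binary", factors=["group"])
    fit = fit_glmm_logit(df, spec, fix_sigma_u=0.0)
    # sum coding: the SVI-vs-S contrast is twice the group coefficient
    assert 2 * fit.beta[1] == pytest.approx(np.log(16.0), abs=1e-4)
    em = emm_contrasts(fit, compare="group")
    assert em.contrasts.loc[0, "estimate"] == pytest.approx(np.log(16.0), abs=1e-4)


def test_sigma_zero_data_matches_plain_logistic_oracle():
    df, y, X, beta_true = logistic_cluster_data(seed=0, sigma_u=0.0)
    spec = ModelSpec(response="direction_binary", factors=["group", "posture", "age_months"])
    fit = fit_glmm_logit(df, spec, response=y)
    assert fit.sigma_u < 0.05

    import statsmodels.api as sm

    ref = sm.Logit(y, X).fit(disp=0)
    assert np.abs(fit.beta - ref.params).max() < 1e-4
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)


def test_separation_warns():
    df = _two_by_two(10, 10, 10, 10)  # every response = 1
    spec = ModelSpec(response="direction_binary", factors=["group"])
    with pytest.warns(UserWarning, match="separation"):
        fit = fit_glmm_logit(df, spec, fix_sigma_u=0.0)
    assert fit.warnings


def test_quadrature_increments_shrink():
    df, y, _, _ = logistic_cluster_data(seed=3, sigma_u=0.8)
    spec = ModelSpec(response="direction_binary", factors=["group", "posture", "age_months"])
    betas = {}
    for q in (1, 5, 21):
        betas[q] = fit_glmm_logit(df, spec, n_quad=q, response=y).beta
    step1 = np.linalg.norm(betas[5] - betas[1])
    step2 = np.linalg.norm(betas[21] - betas[5])
    assert step2 <= step1 + 1e-12


def test_loglik_at_optimum_dominates_truth():
    df, y, _, beta_true = logistic_cluster_data(seed=4, sigma_u=0.6)
    spec = ModelSpec(response="direction_binary", factors=["group", "posture", "age_months"])
    fit = fit_glmm_logit(df, spec, n_quad=7, response=y)
    ll = _AgqLoglik(y, fit.design.X, df["participant_id"].to_numpy(), 7)
    assert fit.loglik >= ll(np.concatenate([beta_true, [0.6]])) - 1e-8


def test_matches_lme4_glmer_oracle(tmp_path):
    """Cross-check fixed effects and sigma_u against glmer on the same data."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    df, y, _, _ = logistic_cluster_data(seed=5, n_clusters=15, per_cluster=16, sigma_u=0.7)
    out = df.copy()
    out["y"] = y
    csv = tmp_path / "d.csv"
    out.to_csv(csv, index=False)
    script = tmp_path / "check.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$group <- factor(d$group, levels=c("SVI","S"))
        d$posture <- factor(d$posture, levels=c("uncrossed","crossed"))
        contrasts(d$group) <- contr.sum(2)
        contrasts(d$posture) <- contr.sum(2)
        d$age_c <- d$age_months - mean(d$age_months)
        m <- glmer(y ~ group*posture*age_c + (1|participant_id),
                   data=d, family=binomial, nAGQ=9)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), sep="\\n")
    """))
    res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    vals = np.array([float(v) for v in res.stdout.split()])
    spec = ModelSpec(response="direction_binary", factors=["group", "posture", "age_months"])
    fit = fit_glmm_logit(df, spec, n_quad=9, response=y)
    assert np.abs(fit.beta - vals[:-1]).max() < 5e-3
    assert fit.sigma_u == pytest.approx(vals[-1], abs=5e-3)


def test_bad_inputs():
    df = _two_by_two(5, 10, 5, 10)
    spec = ModelSpec(response="direction_binary", factors=["group"])
    df2 = df.copy()
    df2["y"] = 0.5
    with pytest.raises(ValueError, match="binary"):
        fit_glmm_logit(df2, spec)
    one = df[df.participant_id == "SVI0"]
    with pytest.raises(ValueError, match="participants"):
        fit_glmm_logit(one, spec)
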