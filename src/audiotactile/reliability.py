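"""Inter-observer agreement: Cohen's kappa, weighted kappa, RT agreement.

Two independent observers code each trial's response side (left / right /
null) and modality (arm-hand / eye-head / null) from video.  Agreement on
these nominal codes is summarized by Cohen's kappa and, for ordered codes,
weighted kappa; agreement on the coded latencies by the Pearson correlation
and the mean signed difference (rater 1 − rater 2).

Confidence intervals use the large-sample (Fleiss-Cohen) asymptotic
standard error with normal quantiles, truncated to the parameter range.
A bootstrap CI is available behind ``ci="bootstrap"`` for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementTable",
    "KappaResult",
    "RtAgreement",
    "agreement_table",
    "cohen_kappa",
    "weighted_kappa",
    "rt_agreement",
]


class DegenerateTableError(ValueError):
    """Kappa undefined: expected chance agreement equals 1."""


@dataclass
class AgreementTable:
    """Square rater-1 x rater-2 contingency table of nominal codes."""

    counts: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match the label set")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> float:
        return float(self.counts.sum())


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    weighted: bool = False
    weight_scheme: str = "none"


@dataclass
class RtAgreement:
    pearson_r: float
    r_ci: tuple[float, float]
    mean_signed_diff_s: float
    diff_ci: tuple[float, float]
    n: int


def agreement_table(codes1, codes2, labels: list[str] | None = None) -> AgreementTable:
    """Cross-tabulate two equal-length code sequences."""
    c1 = pd.Series(codes1).astype(str)
    c2 = pd.Series(codes2).astype(str)
    if len(c1) != len(c2):
        raise ValueError("code sequences must be paired (equal length)")
    if labels is None:
        labels = sorted(set(c1) | set(c2))
    tab = pd.crosstab(
        pd.Categorical(c1, categories=labels),
        pd.Categorical(c2, categories=labels),
        dropna=False,
    ).reindex(index=labels, columns=labels, fill_value=0)
    return AgreementTable(tab.to_numpy(float), list(labels))


def _kappa_from_weights(table: AgreementTable, w: np.ndarray) -> tuple[float, float]:
    """Weighted kappa and its Fleiss-Cohen asymptotic SE.

    ``w`` holds *agreement* weights (1 on the diagonal).  With the identity
    weight matrix this reduces to unweighted kappa and its SE.
    """
    n = table.n
    if n < 2:
        raise ValueError("kappa requires a total count of at least 2")
    p = table.counts / n
    pi = p.sum(axis=1)  # rater 1 marginals
    pj = p.sum(axis=0)  # rater 2 marginals
    po = float((w * p).sum())
    pe = float((w * np.outer(pi, pj)).sum())
    if pe >= 1.0 - 1e-12:
        raise DegenerateTableError("chance agreement is 1; kappa undefined")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt large-sample variance of weighted kappa
    wi = (w * pj[None, :]).sum(axis=1)  # row-wise expected weights
    wj = (w * pi[:, None]).sum(axis=0)
    term = (p * (w - (wi[:, None] + wj[None, :]) * (1.0 - kappa)) ** 2).sum()
    var = (term - (kappa - pe * (1.0 - kappa)) ** 2) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return float(kappa), se


def _weights(k: int, scheme: str) -> np.ndarray:
    i = np.arange(k)
    d = np.abs(i[:, None] - i[None, :]).astype(float)
    if scheme == "none":
        return (d == 0).astype(float)
    if k == 1:
        return np.ones((1, 1))
    if scheme == "linear":
        return 1.0 - d / (k - 1)
    if scheme == "quadratic":
        return 1.0 - (d / (k - 1)) ** 2
    raise ValueError(f"unknown weight scheme {scheme!r}")


def cohen_kappa(table: AgreementTable, conf_level: float = 0.95) -> KappaResult:
    """Unweighted Cohen's kappa with an asymptotic confidence interval."""
    kappa, se = _kappa_from_weights(table, _weights(len(table.labels), "none"))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    return KappaResult(
        kappa=kappa,
        se=se,
        ci_low=max(kappa - z * se, -1.0),
        ci_high=min(kappa + z * se, 1.0),
    )


def weighted_kappa(
    table: AgreementTable, scheme: str = "linear", conf_level: float = 0.95
) -> KappaResult:
    """Weighted kappa with disagreement weights |i-j|/(k-1) (or squared)."""
    if scheme not in ("linear", "quadratic"):
        raise ValueError("scheme must be 'linear' or 'quadratic'")
    kappa, se = _kappa_from_weights(table, _weights(len(table.labels), scheme))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    return KappaResult(
        kappa=kappa,
        se=se,
        ci_low=max(kappa - z * se, -1.0),
        ci_high=min(kappa + z * se, 1.0),
        weighted=True,
        weight_scheme=scheme,
    )


def rt_agreement(rt1, rt2, conf_level: float = 0.95) -> RtAgreement:
    """Pearson correlation (Fisher-z CI) and mean signed RT difference r1 − r2."""
    x = np.asarray(rt1, dtype=float)
    y = np.asarray(rt2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("RT lists must be paired 1-d arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired RTs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in one rater's RTs")
    r = float(stats.pearsonr(x, y).statistic)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = z / np.sqrt(n - 3)
    r_ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))

    d = x - y
    md = float(d.mean())
    half_d = z * d.std(ddof=1) / np.sqrt(n)
    return RtAgreement(
        pearson_r=r,
        r_ci=r_ci,
        mean_signed_diff_s=md,
        diff_ci=(md - half_d, md + half_d),
        n=n,
    )
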