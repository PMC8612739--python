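"""Fixed-effect design matrices with sum-to-zero factor coding.

Type III Wald tests are only meaningful under sum-to-zero (deviation)
contrasts, so the model machinery builds its own design matrices rather
than relying on a formula engine's default treatment coding.  A model is a
full factorial over the named predictors: every main effect plus every
interaction up to the full order.  Categorical predictors contribute
``k - 1`` deviation-coded columns (level ``j`` column = +1, last level =
−1); numeric predictors (age in months, centered) contribute one column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "DesignMatrix", "build_design"]

#: factor level orders used throughout (reference = last level under sum coding)
FACTOR_LEVELS = {
    "group": ["SVI", "S"],
    "posture": ["uncrossed", "crossed"],
}


@dataclass
class ModelSpec:
    """What to fit: response, factorial fixed effects, conditions included."""

    response: str  # 'direction_binary' or 'rt_seconds'
    factors: list[str] = field(default_factory=lambda: ["group", "posture", "age_months"])
    conditions: list[str] | None = None  # subset of trials to model
    condition_levels: list[str] | None = None  # level order when 'condition' is a factor
    center_age: bool = True

    def __post_init__(self):
        if self.response not in ("direction_binary", "rt_seconds"):
            raise ValueError(f"unknown response {self.response!r}")
        allowed = {"group", "posture", "condition", "age_months"}
        bad = set(self.factors) - allowed
        if bad:
            raise ValueError(f"unknown model factors {sorted(bad)}")


@dataclass
class DesignMatrix:
    X: np.ndarray
    columns: list[str]
    term_slices: dict[str, slice]
    factor_levels: dict[str, list[str]]
    age_center: float

    @property
    def terms(self) -> list[str]:
        return [t for t in self.term_slices if t != "intercept"]


def _deviation_codes(values: pd.Series, levels: list[str]) -> np.ndarray:
    """n x (k-1) sum-to-zero contrast columns."""
    k = len(levels)
    out = np.zeros((len(values), k - 1))
    idx = pd.Categorical(values, categories=levels).codes
    if (idx < 0).any():
        bad = sorted(set(values[idx < 0]))
        raise ValueError(f"values outside factor levels: {bad}")
    for j in range(k - 1):
        out[idx == j, j] = 1.0
    out[idx == k - 1, :] = -1.0
    return out


def build_design(
    trials: pd.DataFrame,
    spec: ModelSpec,
    levels_override: dict[str, list[str]] | None = None,
    age_center_override: float | None = None,
) -> DesignMatrix:
    """Full-factorial sum-coded design matrix for ``trials`` under ``spec``.

    The overrides let prediction grids (estimated marginal means) reuse the
    factor coding and age centering of the fitted data.
    """
    levels: dict[str, list[str]] = {}
    blocks: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    age_center = 0.0
    for f in spec.factors:
        if f == "age_months":
            age = trials["age_months"].to_numpy(float)
            if age_center_override is not None:
                age_center = age_center_override
            else:
                age_center = float(age.mean()) if spec.center_age else 0.0
            blocks[f] = (age - age_center)[:, None]
            names[f] = ["age_c"]
        else:
            if levels_override and f in levels_override:
                lv = levels_override[f]
            elif f == "condition":
                lv = spec.condition_levels or sorted(trials["condition"].unique())
            else:
                lv = FACTOR_LEVELS[f]
            levels[f] = lv
            blocks[f] = _deviation_codes(trials[f], lv)
            names[f] = [f"{f}[{l}]" for l in lv[:-1]]

    cols = [np.ones((len(trials), 1))]
    colnames = ["(Intercept)"]
    term_slices: dict[str, slice] = {"intercept": slice(0, 1)}
    pos = 1
    for order in range(1, len(spec.factors) + 1):
        for combo in combinations(spec.factors, order):
            # columnwise Khatri-Rao product over the chosen factors
            mats = [blocks[f] for f in combo]
            nm = [names[f] for f in combo]
            prod = mats[0]
            prod_names = nm[0]
            for m, mn in zip(mats[1:], nm[1:]):
                prod = np.einsum("ni,nj->nij", prod, m).reshape(len(trials), -1)
                prod_names = [f"{a}:{b}" for a in prod_names for b in mn]
            cols.append(prod)
            colnames += prod_names
            term = ":".join(combo)
            term_slices[term] = slice(pos, pos + prod.shape[1])
            pos += prod.shape[1]
    X = np.hstack(cols)
    return DesignMatrix(X=X, columns=colnames, term_slices=term_slices,
                        factor_levels=levels, age_center=age_center)
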