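"""Random-intercept mixed models, Type III Wald tables and EMM contrasts.

Two model families cover the study's inferential analyses:

* a **logistic GLMM** for the binary orienting direction, with a participant
  random intercept integrated out by adaptive Gauss-Hermite quadrature
  (``n_quad = 1`` is the Laplace approximation, the conventional default for
  binomial mixed models);
* a **linear mixed model** for response latencies, fitted by profiled
  REML/ML over the single variance ratio with closed-form GLS coefficients
  at the optimum.

Fixed effects use sum-to-zero contrasts with age centered, so the Type III
Wald chi-square of a term is the quadratic form ``b' V^{-1} b`` over that
term's coefficient block — the direct analogue of ``car::Anova(type = 3)``.
Estimated marginal means average the linear predictor over the levels of
the non-conditioning factors with equal weights; pairwise contrasts within
each conditioning cell are Bonferroni-corrected with the stated family
size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, roots_hermite

from .design import DesignMatrix, ModelSpec, build_design

__all__ = [
    "GlmmFit",
    "LmmFit",
    "WaldTable",
    "EmmContrasts",
    "fit_glmm_logit",
    "fit_lmm",
    "wald_type3",
    "emm_contrasts",
]

_LOGISTIC_SD = np.pi / np.sqrt(3.0)  # residual SD of the latent logistic scale


class NonIdentifiedError(RuntimeError):
    """Variance components cannot be separated (one observation per cluster)."""


class AliasedTermError(ValueError):
    """A model term's covariance block is singular (aliased coefficients)."""


@dataclass
class GlmmFit:
    beta: np.ndarray
    sigma_u: float
    vcov_beta: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    n_participants: int
    design: DesignMatrix
    spec: ModelSpec
    n_quad: int
    warnings: list[str] = field(default_factory=list)

    kind: str = "glmm"

    @property
    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.vcov_beta))
        return pd.DataFrame({"estimate": self.beta, "se": se}, index=self.design.columns)


@dataclass
class LmmFit:
    beta: np.ndarray
    sigma_u: float
    sigma_resid: float
    vcov_beta: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    n_participants: int
    design: DesignMatrix
    spec: ModelSpec
    method: str

    kind: str = "lmm"

    @property
    def edf(self) -> float:
        """Approximate error df: observations minus fixed rank minus clusters."""
        return float(self.n_obs - self.design.X.shape[1] - self.n_participants + 1)

    @property
    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.vcov_beta))
        return pd.DataFrame({"estimate": self.beta, "se": se}, index=self.design.columns)


@dataclass
class WaldTable:
    table: pd.DataFrame  # index: term; columns: chi2, df, p

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


@dataclass
class EmmContrasts:
    emmeans: pd.DataFrame
    contrasts: pd.DataFrame
    correction_n: int


# ---------------------------------------------------------------------------
# logistic GLMM via adaptive Gauss-Hermite quadrature


class _AgqLoglik:
    """Marginal log-likelihood of a random-intercept logit model.

    The participant intercept enters as ``sigma * u`` with ``u ~ N(0, 1)``;
    per cluster the integral over ``u`` is evaluated by Gauss-Hermite
    quadrature adapted at the conditional mode (found by a damped Newton
    iteration, vectorized across clusters and warm-started between calls).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray, n_quad: int):
        self.y = y.astype(float)
        self.X = X
        codes, _ = pd.factorize(groups)
        self.idx = codes
        self.n_groups = codes.max() + 1
        self.nodes, self.weights = roots_hermite(n_quad)
        self.logw = np.log(self.weights) + self.nodes**2
        self._u = np.zeros(self.n_groups)  # warm start for the inner modes
        self.ysum = np.bincount(self.idx, weights=self.y, minlength=self.n_groups)

    def _cluster_f(self, eta0: np.ndarray, sigma: float, u: np.ndarray) -> np.ndarray:
        """f_i(u) = log p(y_i | u) + log phi(u), vector over clusters."""
        eta = eta0 + sigma * u[self.idx]
        # sum_j [y*eta - log(1 + e^eta)]
        ll = self.y * eta - np.logaddexp(0.0, eta)
        out = np.bincount(self.idx, weights=ll, minlength=self.n_groups)
        return out - 0.5 * u**2 - 0.5 * np.log(2 * np.pi)

    def __call__(self, params: np.ndarray) -> float:
        beta, sigma = params[:-1], abs(params[-1])
        eta0 = self.X @ beta
        u = self._u.copy()
        if sigma == 0.0:
            u[:] = 0.0
            hess = -np.ones(self.n_groups)
        else:
            for _ in range(100):
                eta = eta0 + sigma * u[self.idx]
                mu = expit(eta)
                grad = sigma * (self.ysum - np.bincount(self.idx, weights=mu, minlength=self.n_groups)) - u
                w = np.bincount(self.idx, weights=mu * (1 - mu), minlength=self.n_groups)
                hess = -(sigma**2) * w - 1.0
                step = grad / hess
                # damped Newton: halve until f does not decrease
                f_old = self._cluster_f(eta0, sigma, u)
                scale = 1.0
                for _ in range(20):
                    u_new = u - scale * step
                    if (self._cluster_f(eta0, sigma, u_new) >= f_old - 1e-12).all():
                        break
                    scale *= 0.5
                u = u_new
                if np.max(np.abs(grad)) < 1e-9:
                    break
            eta = eta0 + sigma * u[self.idx]
            mu = expit(eta)
            w = np.bincount(self.idx, weights=mu * (1 - mu), minlength=self.n_groups)
            hess = -(sigma**2) * w - 1.0
        self._u = u
        s = 1.0 / np.sqrt(-hess)
        # adaptive nodes u_k = u* + sqrt(2) s z_k
        fk = np.empty((len(self.nodes), self.n_groups))
        for k, z in enumerate(self.nodes):
            fk[k] = self._cluster_f(eta0, sigma, u + np.sqrt(2.0) * s * z)
        m = fk.max(axis=0)
        li = m + np.log(np.sum(np.exp(fk - m + self.logw[:, None]), axis=0))
        li += 0.5 * np.log(2.0) + np.log(s)
        return float(li.sum())


def fit_glmm_logit(
    trials: pd.DataFrame,
    spec: ModelSpec,
    n_quad: int = 1,
    response: np.ndarray | None = None,
    tol: float = 1e-8,
    fix_sigma_u: float | None = None,
) -> GlmmFit:
    """Fit a random-intercept logistic GLMM by maximum likelihood.

    ``response`` overrides the binary outcome column (default: the frame's
    ``y`` column).  ``n_quad`` Gauss-Hermite nodes adapt at each cluster's
    conditional mode; 1 node is the Laplace approximation.  ``fix_sigma_u``
    constrains the random-intercept SD instead of estimating it
    (``fix_sigma_u=0`` reduces the model to ordinary logistic regression).
    """
    y = np.asarray(response if response is not None else trials["y"], dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("GLMM response must be binary 0/1 with no missing values")
    if trials["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    dm = build_design(trials, spec)
    ll = _AgqLoglik(y, dm.X, trials["participant_id"].to_numpy(), n_quad)

    p = dm.X.shape[1]
    sigma0 = 0.5 if fix_sigma_u is None else fix_sigma_u
    sigma_bounds = (0.0, None) if fix_sigma_u is None else (fix_sigma_u, fix_sigma_u)
    x0 = np.concatenate([np.zeros(p), [sigma0]])
    nll = lambda th: -ll(th)
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B",
        bounds=[(None, None)] * p + [sigma_bounds],
        options={"ftol": tol * 1e-4, "gtol": 1e-9, "maxiter": 1000, "maxfun": 50000},
    )
    beta, sigma = res.x[:-1], abs(res.x[-1])

    warns: list[str] = []
    eta = dm.X @ beta
    if np.abs(beta).max() > 12 or (np.abs(eta) > 12).mean() > 0.5:
        warns.append(
            "possible complete separation: extreme coefficients; consider a penalized fit"
        )
        warnings.warn(warns[-1], stacklevel=2)

    if fix_sigma_u is not None:
        nll_beta = lambda b: -ll(np.concatenate([b, [fix_sigma_u]]))
        vcov = np.linalg.inv(_numdiff_hessian(nll_beta, beta))
    else:
        H = _numdiff_hessian(nll, res.x)
        vcov = _safe_inverse(H, p, sigma)
    return GlmmFit(
        beta=beta, sigma_u=sigma, vcov_beta=vcov, loglik=-res.fun,
        converged=bool(res.success), n_obs=len(y),
        n_participants=trials["participant_id"].nunique(),
        design=dm, spec=spec, n_quad=n_quad, warnings=warns,
    )


def _numdiff_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    steps = h * np.maximum(1.0, np.abs(x))

    def fd(i, j):
        ei = np.zeros(n); ei[i] = steps[i]
        ej = np.zeros(n); ej[j] = steps[j]
        if i == j:
            return (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
        return (
            f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
        ) / (4 * steps[i] * steps[j])

    for i in range(n):
        for j in range(i + 1):
            H[i, j] = H[j, i] = fd(i, j)
    return H


def _safe_inverse(H: np.ndarray, p: int, sigma: float) -> np.ndarray:
    """Beta block of the inverse observed information, robust to a boundary sigma."""
    try:
        if sigma < 1e-6:
            # sigma on the boundary: condition on it and invert the beta block
            return np.linalg.inv(H[:p, :p])
        return np.linalg.inv(H)[:p, :p]
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)[:p, :p]


# ---------------------------------------------------------------------------
# linear mixed model: profiled (RE)ML over the variance ratio


def _lmm_profile(lam: float, y, X, idx, n_groups, reml: bool):
    """Closed-form GLS pieces at variance ratio lam = sigma_u^2 / sigma_e^2.

    With V0 = I + lam * Z Z' (Z the cluster indicator), each cluster block
    inverts analytically: (I + lam J)^{-1} = I - lam/(1 + lam n_i) J.
    Returns the -2 log-(restricted-)likelihood profile and the GLS pieces.
    """
    n, p = X.shape
    n_i = np.bincount(idx, minlength=n_groups).astype(float)
    c = lam / (1.0 + lam * n_i)  # per-cluster shrinkage of the sums
    sx = np.vstack([np.bincount(idx, weights=X[:, j], minlength=n_groups) for j in range(p)]).T
    sy = np.bincount(idx, weights=y, minlength=n_groups)
    A = X.T @ X - (sx * c[:, None]).T @ sx          # X' V0^{-1} X
    b = X.T @ y - sx.T @ (c * sy)                   # X' V0^{-1} y
    beta = np.linalg.solve(A, b)
    e = y - X @ beta
    se = np.bincount(idx, weights=e, minlength=n_groups)
    Q = float(e @ e - c @ se**2)                    # e' V0^{-1} e
    logdetV0 = float(np.sum(np.log1p(lam * n_i)))
    if reml:
        dof = n - p
        sig2 = Q / dof
        sign, logdetA = np.linalg.slogdet(A)
        m2ll = dof * np.log(2 * np.pi * sig2) + logdetV0 + logdetA + dof
        # lme4's REML criterion drops the fixed-effects normalization |X'X|;
        # constant in lam, so irrelevant to the optimum
    else:
        sig2 = Q / n
        m2ll = n * np.log(2 * np.pi * sig2) + logdetV0 + n
    return m2ll, beta, sig2, A


def fit_lmm(trials: pd.DataFrame, spec: ModelSpec, method: str = "REML") -> LmmFit:
    """Fit a participant random-intercept LMM to response latencies.

    The single variance ratio ``lambda = sigma_u^2 / sigma_resid^2`` is
    profiled out: fixed effects and the residual variance have closed GLS
    forms at each ``lambda``, leaving a 1-d criterion optimized by bounded
    scalar search (boundary ``lambda = 0`` checked explicitly).  The
    coefficient covariance is the GLS covariance at the optimum, as
    reported by the standard mixed-model toolchain.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    y = trials["rt_s"].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("rt_s must be present for all modelled rows")
    if trials["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    idx, _ = pd.factorize(trials["participant_id"].to_numpy())
    n_groups = idx.max() + 1
    if np.bincount(idx).max() <= 1:
        raise NonIdentifiedError(
            "one observation per participant: sigma_u and sigma_resid are not identified"
        )
    dm = build_design(trials, spec)
    X = dm.X
    reml = method == "REML"

    def crit(loglam: float) -> float:
        return _lmm_profile(np.exp(loglam), y, X, idx, n_groups, reml)[0]

    # coarse grid then local refinement over log-lambda; explicit boundary check
    grid = np.linspace(-12.0, 6.0, 37)
    vals = [crit(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        crit, bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    m2ll, beta, sig2, A = _lmm_profile(lam, y, X, idx, n_groups, reml)
    m2ll0, beta0, sig20, A0 = _lmm_profile(0.0, y, X, idx, n_groups, reml)
    if m2ll0 <= m2ll:
        lam, m2ll, beta, sig2, A = 0.0, m2ll0, beta0, sig20, A0

    return LmmFit(
        beta=beta,
        sigma_u=float(np.sqrt(lam * sig2)),
        sigma_resid=float(np.sqrt(sig2)),
        vcov_beta=sig2 * np.linalg.inv(A),
        loglik=-0.5 * m2ll,
        converged=True,
        n_obs=len(y),
        n_participants=int(n_groups),
        design=dm, spec=spec, method=method,
    )


# ---------------------------------------------------------------------------
# Type III Wald tests


def wald_type3(fit: GlmmFit | LmmFit) -> WaldTable:
    """Per-term Type III Wald chi-square table (requires sum-to-zero coding)."""
    rows = []
    for term, sl in fit.design.term_slices.items():
        if term == "intercept":
            continue
        b = fit.beta[sl]
        V = fit.vcov_beta[sl, sl]
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as e:
            raise AliasedTermError(f"singular covariance block for term {term!r}") from e
        if chi2 < 0:
            raise AliasedTermError(f"indefinite covariance block for term {term!r}")
        df = sl.stop - sl.start
        rows.append((term, chi2, df, float(stats.chi2.sf(chi2, df))))
    tab = pd.DataFrame(rows, columns=["term", "chi2", "df", "p"]).set_index("term")
    return WaldTable(tab)


# ---------------------------------------------------------------------------
# estimated marginal means and contrasts


def _emm_rows(fit, cells: pd.DataFrame) -> np.ndarray:
    """Linear-predictor rows for EMM cells, averaging over unlisted factors."""
    spec = fit.spec
    dm = fit.design
    cat_factors = [f for f in spec.factors if f != "age_months"]
    free = [f for f in cat_factors if f not in cells.columns]
    # full grid over the free factors, averaged with equal weights
    grids = [dm.factor_levels[f] for f in free]
    combos = [[]]
    for g in grids:
        combos = [c + [lv] for c in combos for lv in g]
    L = np.zeros((len(cells), dm.X.shape[1]))
    for r, (_, cell) in enumerate(cells.iterrows()):
        rows = []
        for combo in combos:
            rec = {f: cell[f] for f in cells.columns}
            rec.update(dict(zip(free, combo)))
            rec["age_months"] = dm.age_center  # age_c = 0 at the sample mean age
            rows.append(rec)
        grid = pd.DataFrame(rows)
        gdm = build_design(
            grid, spec, levels_override=dm.factor_levels, age_center_override=dm.age_center
        )
        L[r] = gdm.X.mean(axis=0)
    return L


def emm_contrasts(
    fit: GlmmFit | LmmFit,
    compare: str,
    by: list[str] | None = None,
    correction_n: int | None = None,
) -> EmmContrasts:
    """Pairwise EMM contrasts of ``compare`` within each ``by`` cell.

    Estimates are on the linear-predictor scale (log-odds for the GLMM,
    seconds for the LMM).  P-values use the normal reference for the GLMM
    and a t reference with the model's approximate error df for the LMM,
    Bonferroni-multiplied by ``correction_n`` (default: the number of
    contrasts in the family).  Effect sizes standardize the contrast by the
    model sigma (residual SD for the LMM, the logistic scale SD for the
    GLMM), following the EMM effect-size convention.
    """
    by = list(by or [])
    dm = fit.design
    for f in [compare, *by]:
        if f not in dm.factor_levels:
            raise ValueError(f"factor {f!r} not in the fitted model")

    # EMM grid: all (by x compare) cells
    lv_by = [dm.factor_levels[f] for f in by]
    cells = [[]]
    for g in lv_by:
        cells = [c + [lv] for c in cells for lv in g]
    grid_rows = []
    for c in cells:
        for lv in dm.factor_levels[compare]:
            grid_rows.append(dict(zip(by, c)) | {compare: lv})
    cells_df = pd.DataFrame(grid_rows)
    L = _emm_rows(fit, cells_df)
    emm = L @ fit.beta
    emm_se = np.sqrt(np.einsum("ij,jk,ik->i", L, fit.vcov_beta, L))
    emm_df = cells_df.assign(emmean=emm, se=emm_se)

    sigma = fit.sigma_resid if fit.kind == "lmm" else _LOGISTIC_SD
    lv_cmp = dm.factor_levels[compare]
    pairs = [(a, b) for i, a in enumerate(lv_cmp) for b in lv_cmp[i + 1 :]]
    con_rows = []
    for c in cells:
        cell_mask = np.ones(len(cells_df), bool)
        for f, lv in zip(by, c):
            cell_mask &= (cells_df[f] == lv).to_numpy()
        for a, b in pairs:
            ia = np.where(cell_mask & (cells_df[compare] == a).to_numpy())[0][0]
            ib = np.where(cell_mask & (cells_df[compare] == b).to_numpy())[0][0]
            l = L[ia] - L[ib]
            est = float(l @ fit.beta)
            se = float(np.sqrt(l @ fit.vcov_beta @ l))
            tstat = est / se
            if fit.kind == "lmm":
                p = 2.0 * float(stats.t.sf(abs(tstat), fit.edf))
            else:
                p = 2.0 * float(stats.norm.sf(abs(tstat)))
            con_rows.append(
                dict(zip(by, c))
                | {
                    "contrast": f"{a} - {b}",
                    "estimate": est,
                    "se": se,
                    "stat": tstat,
                    "p": p,
                    "effect_size": est / sigma,
                }
            )
    con = pd.DataFrame(con_rows)
    n_corr = correction_n if correction_n is not None else len(con)
    con["p_adj"] = np.minimum(1.0, con["p"] * n_corr)
    return EmmContrasts(emmeans=emm_df, contrasts=con, correction_n=n_corr)
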