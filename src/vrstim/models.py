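"""Linear mixed-effects modelling of vitals and oculomotor features.

All models are Gaussian LMEMs fitted by maximum likelihood (not REML, so
that likelihood-ratio tests across nested random structures are valid).

* For each vital sign a ladder of three models is compared: (1) random
  participant intercept; (2) plus an uncorrelated random slope of time;
  (3) plus the intercept-slope correlation. Each extension is retained when
  its likelihood-ratio test is significant.
* Questionnaire ratings are added to the chosen vitals model one scale at a
  time, with Holm-adjusted p-values across scales.
* For each oculomotor feature eight models are fitted (a zero model, three
  single-predictor models, the full model with time, target and video type,
  and the three leave-one-out models) and summarised by marginal and
  conditional R2 (variance explained by the fixed effects alone vs fixed
  plus random effects), the effect-size criterion used instead of p-values
  on very large windowed samples.

Fixed-effect p-values come from conditional t-tests with residual degrees
of freedom (``n_obs - rank(X)``); the method is recorded in the fit
metadata. Likelihood-ratio tests for variance components use the naive
chi-squared reference, which is conservative at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LMEMFit",
    "R2Pair",
    "RANDOM_STRUCTURES",
    "fit_lmem",
    "nakagawa_r2",
    "select_vitals_model",
    "add_rating_effects",
    "oculomotor_model_suite",
    "holm_adjust",
    "OCULOMOTOR_RESPONSES",
    "MODEL_SUITE",
]

RANDOM_STRUCTURES = ("intercept", "intercept_slope_uncorrelated", "intercept_slope_correlated")

OCULOMOTOR_RESPONSES = ("n_fix_per_s", "fix_dur_ms_per_s", "sacc_amp_deg", "fix_sacc_ratio")

# the eight-model comparison for each oculomotor response
MODEL_SUITE: dict[str, tuple[str, ...]] = {
    "zero": (),
    "time": ("time",),
    "target": ("target",),
    "video_type": ("video_type",),
    "full": ("time", "target", "video_type"),
    "full_minus_time": ("target", "video_type"),
    "full_minus_target": ("time", "video_type"),
    "full_minus_video_type": ("time", "target"),
}


@dataclass(frozen=True)
class R2Pair:
    """Nakagawa marginal and conditional R2 of a mixed model."""

    marginal: float
    conditional: float


@dataclass
class LMEMFit:
    """A fitted LMEM: estimates, variance components and fit statistics."""

    response: str
    fixed_effects: tuple[str, ...]
    random_structure: str
    params: pd.DataFrame  # term, beta, se, t, df, p
    cov_re: np.ndarray  # random-effect covariance (data scale)
    resid_var: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool
    df_method: str = "residual"
    exog: np.ndarray = field(repr=False, default=None)
    fe_params: np.ndarray = field(repr=False, default=None)
    exog_re: np.ndarray = field(repr=False, default=None)

    @property
    def loglik_df(self) -> int:
        """Number of estimated parameters (for likelihood-ratio tests)."""
        n_cov = {"intercept": 1, "intercept_slope_uncorrelated": 2,
                 "intercept_slope_correlated": 3}[self.random_structure]
        return len(self.fe_params) + n_cov + 1


def _term_expr(term: str) -> str:
    if term == "video_type":
        return "C(video_type)"
    if term == "age_time":
        return "time:age"
    return f"Q('{term}')" if not term.isidentifier() else term


def fit_lmem(
    data: pd.DataFrame,
    response: str,
    fixed_effects: tuple[str, ...] | list[str] = ("time",),
    random_structure: str = "intercept",
    group_col: str = "participant_id",
) -> LMEMFit:
    """Fit one LMEM by maximum likelihood.

    ``fixed_effects`` tokens: ``time`` (numeric), ``video_type`` (unordered
    categorical, first level as reference), ``target`` (0/1 dummy),
    ``age_time`` (the age x time interaction), or any numeric column name
    (e.g. a rating scale). The intercept is always included. Constant
    covariates (e.g. a single video) are dropped with a warning. A fit with
    a variance component estimated at (numerically) zero is flagged
    singular but returned.
    """
    if random_structure not in RANDOM_STRUCTURES:
        raise ValueError(f"unknown random structure {random_structure!r}")
    fixed_effects = tuple(fixed_effects)
    needed = {response, group_col}
    for term in fixed_effects:
        needed.update({"time", "age"} if term == "age_time" else {term})
    missing = needed - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns: {sorted(missing)}")
    use_cols = sorted(needed | ({"time"} if random_structure != "intercept" else set()))
    df = data[use_cols].dropna().copy()
    if df[group_col].nunique() < 2:
        raise ValueError("need >= 2 participants to fit a mixed model")

    kept = []
    for term in fixed_effects:
        col = "video_type" if term == "video_type" else ("time" if term == "age_time" else term)
        if col in df.columns and df[col].nunique() < 2:
            warnings.warn(f"dropping constant fixed effect {term!r}", stacklevel=2)
            continue
        kept.append(term)
    rhs = " + ".join(_term_expr(t) for t in kept) if kept else "1"
    formula = f"Q('{response}') ~ {rhs}"

    re_formula = "1" if random_structure == "intercept" else "1 + time"
    model = MixedLM.from_formula(formula, data=df, groups=df[group_col], re_formula=re_formula)

    free = None
    if random_structure == "intercept_slope_uncorrelated":
        free = MixedLMParams.from_components(
            fe_params=np.ones(model.exog.shape[1]), cov_re=np.eye(2)
        )
    # optimizers differ in robustness; accept the first converged fit and
    # otherwise keep the best log-likelihood among those that ran
    # (powell does not honour the covariance constraint, so it is excluded
    # for the constrained uncorrelated-slope model)
    methods = ("lbfgs", "bfgs", "cg") if free is not None else ("lbfgs", "bfgs", "cg", "powell")
    res = None
    err: Exception | None = None
    for method in methods:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = model.fit(reml=False, free=free, method=[method])
        except Exception as exc:
            err = exc
            continue
        if not np.isfinite(cand.llf):  # spurious boundary optimum
            continue
        if cand.converged:
            res = cand
            break
        if res is None or cand.llf > res.llf:
            res = cand
    if res is None:
        raise RuntimeError(f"mixed-model fit failed for {response!r}: {err}") from err

    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        fe = np.asarray(res.fe_params)
        bse = np.asarray(res.bse_fe)
    n_obs = model.exog.shape[0]
    dof = n_obs - np.linalg.matrix_rank(model.exog)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = fe / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    params = pd.DataFrame(
        {"term": model.exog_names, "beta": fe, "se": bse, "t": tvals,
         "df": dof, "p": pvals}
    )
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    singular = bool(np.any(np.diag(cov_re) < 1e-8 * max(res.scale, 1e-12)))
    return LMEMFit(
        response=response,
        fixed_effects=tuple(kept),
        random_structure=random_structure,
        params=params,
        cov_re=cov_re,
        resid_var=float(res.scale),
        loglik=float(res.llf),
        n_obs=n_obs,
        n_groups=int(model.n_groups),
        converged=bool(res.converged),
        singular=singular,
        exog=np.asarray(model.exog),
        fe_params=fe,
        exog_re=np.asarray(model.exog_re),
    )


def nakagawa_r2(fit: LMEMFit) -> R2Pair:
    """Marginal and conditional R2 from the variance decomposition of a fit.

    marginal = var(fixed predictions) / (var(fixed) + var(random) +
    residual variance); conditional replaces the numerator by fixed plus
    random variance. For random-slope models the random-effect variance is
    the average over observations of ``z_i' Sigma z_i``.
    """
    # a model with no fixed effects beyond the intercept explains no
    # variance by construction; avoid floating-point dust
    var_f = 0.0 if not fit.fixed_effects else float(np.var(fit.exog @ fit.fe_params))
    z = fit.exog_re
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", z, fit.cov_re, z)))
    total = var_f + var_r + fit.resid_var
    if total <= 0:
        raise ValueError("total variance is zero; R2 undefined")
    return R2Pair(marginal=var_f / total, conditional=(var_f + var_r) / total)


def _lrt(fit_small: LMEMFit, fit_big: LMEMFit) -> tuple[float, int, float]:
    stat = max(2.0 * (fit_big.loglik - fit_small.loglik), 0.0)
    dof = max(fit_big.loglik_df - fit_small.loglik_df, 1)
    return stat, dof, float(stats.chi2.sf(stat, dof))


def select_vitals_model(
    data: pd.DataFrame,
    response: str,
    fixed_effects: tuple[str, ...] = ("time", "video_type"),
    alpha: float = 0.05,
    group_col: str = "participant_id",
) -> tuple[LMEMFit, pd.DataFrame]:
    """Fit the random-structure ladder and keep each significant extension.

    Model 1: random intercept. Model 2: plus uncorrelated random time
    slope, retained if its likelihood-ratio test against model 1 is
    significant at ``alpha``. Model 3: plus the intercept-slope
    correlation, retained likewise against the current model. A rung that
    fails to converge is skipped with the last converged rung retained.
    Returns the chosen fit and the full ladder report.
    """
    report_rows = []
    chosen = fit_lmem(data, response, fixed_effects, "intercept", group_col)
    report_rows.append({"model": "model1_intercept", "loglik": chosen.loglik,
                        "lr_stat": np.nan, "lr_df": np.nan, "lr_p": np.nan,
                        "converged": chosen.converged, "selected": True})
    for name, structure in (("model2_uncorrelated_slope", "intercept_slope_uncorrelated"),
                            ("model3_correlated_slope", "intercept_slope_correlated")):
        try:
            cand = fit_lmem(data, response, fixed_effects, structure, group_col)
        except Exception as exc:  # non-convergence or singular design
            warnings.warn(f"{name} failed for {response!r}: {exc}", stacklevel=2)
            report_rows.append({"model": name, "loglik": np.nan, "lr_stat": np.nan,
                                "lr_df": np.nan, "lr_p": np.nan, "converged": False,
                                "selected": False})
            break
        stat, dof, p = _lrt(chosen, cand)
        take = cand.converged and p < alpha
        report_rows.append({"model": name, "loglik": cand.loglik, "lr_stat": stat,
                            "lr_df": dof, "lr_p": p, "converged": cand.converged,
                            "selected": take})
        if take:
            for row in report_rows[:-1]:
                row["selected"] = False
            chosen = cand
        else:
            break
    return chosen, pd.DataFrame(report_rows)


def holm_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def add_rating_effects(
    data: pd.DataFrame,
    response: str,
    chosen: LMEMFit,
    ratings: pd.DataFrame,
    group_col: str = "participant_id",
) -> pd.DataFrame:
    """Test each questionnaire scale as an extra fixed effect on a vital sign.

    Each scale is added (one at a time) to the chosen model for
    ``response``; the scale coefficient's conditional t-test p-values are
    Holm-adjusted across scales. Scales constant across participants are
    excluded with a warning.
    """
    scales = [c for c in ratings.columns if c != group_col]
    merged = data.merge(ratings, on=group_col, how="left")
    rows = []
    for scale in scales:
        if ratings[scale].nunique() < 2:
            warnings.warn(f"excluding constant rating scale {scale!r}", stacklevel=2)
            continue
        fit = fit_lmem(merged, response, chosen.fixed_effects + (scale,),
                       chosen.random_structure, group_col)
        row = fit.params[fit.params["term"].str.contains(scale, regex=False)]
        if len(row) != 1:
            raise RuntimeError(f"could not locate coefficient for scale {scale!r}")
        r = row.iloc[0]
        rows.append({"scale": scale, "beta": r["beta"], "se": r["se"], "t": r["t"],
                     "df": r["df"], "p_raw": r["p"]})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def oculomotor_model_suite(
    features: pd.DataFrame,
    responses: tuple[str, ...] = OCULOMOTOR_RESPONSES,
    group_col: str = "participant_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The eight-model comparison per oculomotor feature, by effect size.

    Fits, for every response, the zero model, each single fixed effect
    (time, target, video type), the full model, and the three leave-one-out
    models, all with a participant random intercept, and computes marginal
    and conditional R2 for each. Returns the per-model table and the
    leave-one-out delta-R2 table (``r2m(full) - r2m(full minus effect)``)
    quantifying each predictor's contribution to explained variance.
    """
    results = []
    fits: dict[tuple[str, str], LMEMFit] = {}
    for response in responses:
        for name, fe in MODEL_SUITE.items():
            fit = fit_lmem(features, response, fe, "intercept", group_col)
            r2 = nakagawa_r2(fit)
            fits[(response, name)] = fit
            results.append({"response": response, "model": name,
                            "fixed_effects": "+".join(fit.fixed_effects) or "(none)",
                            "loglik": fit.loglik, "n_obs": fit.n_obs,
                            "r2_marginal": r2.marginal, "r2_conditional": r2.conditional})
    res_df = pd.DataFrame(results)
    deltas = []
    for response in responses:
        sub = res_df[res_df["response"] == response].set_index("model")
        full = sub.at["full", "r2_marginal"]
        for effect in ("time", "target", "video_type"):
            reduced = sub.at[f"full_minus_{effect}", "r2_marginal"]
            deltas.append({"response": response, "effect": effect,
                           "delta_r2_marginal": full - reduced})
    return res_df, pd.DataFrame(deltas)
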