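"""Mixed-effects preference statistics for coded saccade peaks.

Two linear mixed models with a per-subject random intercept carry the
analysis: (1) absolute peak height against the stimulus' angular position,
checking that extracted peaks track the target like real orienting turns
do; (2) signed (preference-coded) peak height against condition and
stimulus presence, whose cell means measure which stimulus of each pair
the animal turns toward.  Post hoc contrasts test each condition-by-period
cell mean against zero with a family-wise adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.formula.api as smf

PERIODS = ("during", "between")


class DesignError(ValueError):
    """The peak table cannot support the requested model."""


@dataclass
class ModelFit:
    """A fitted mixed model with its coefficient and deviance tables."""

    model_id: str
    formula: str
    coefficients: pd.DataFrame  # term, estimate, SE, z, p
    random_effect_var: float
    anova: pd.DataFrame  # term, chisq, df, p (Wald)
    n_obs: int
    n_subjects: int
    result: object  # statsmodels MixedLMResults (or OLS fallback)
    used_mixed: bool = True


def _require_subjects(df: pd.DataFrame, n: int = 2) -> None:
    k = df["subject_id"].nunique()
    if k < n:
        raise DesignError(f"need >= {n} subjects for a random intercept, got {k}")


def _fit_mixed(formula: str, df: pd.DataFrame, model_id: str) -> ModelFit:
    model = smf.mixedlm(formula, data=df, groups=df["subject_id"])
    # derivative-free first: gradient methods can stall on a spurious
    # zero-variance boundary for strongly clustered preference data
    result = model.fit(reml=True, method=["powell", "cg", "lbfgs"], maxiter=1000)
    fe = result.fe_params
    se = result.bse_fe
    coef = pd.DataFrame(
        {
            "term": fe.index,
            "estimate": fe.to_numpy(),
            "SE": se.to_numpy(),
            "z": (fe / se).to_numpy(),
            "p": 2 * scipy.stats.norm.sf(np.abs(fe / se)),
        }
    )
    anova = _wald_anova(result, df)
    return ModelFit(
        model_id=model_id,
        formula=formula,
        coefficients=coef,
        random_effect_var=float(np.atleast_2d(result.cov_re)[0, 0]),
        anova=anova,
        n_obs=len(df),
        n_subjects=df["subject_id"].nunique(),
        result=result,
    )


def _wald_anova(result, df: pd.DataFrame) -> pd.DataFrame:
    """Wald chi-square deviance-analysis table, one row per model term."""
    design_info = result.model.data.design_info
    names = list(result.fe_params.index)
    cov = np.asarray(result.cov_params())[: len(names), : len(names)]
    beta = result.fe_params.to_numpy()
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = list(range(sl.start, sl.stop))
        L = np.zeros((len(idx), len(names)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        est = L @ beta
        V = L @ cov @ L.T
        stat = float(est @ np.linalg.solve(V, est))
        dof = len(idx)
        rows.append(
            {
                "term": term,
                "chisq": stat,
                "df": dof,
                "p": float(scipy.stats.chi2.sf(stat, dof)),
            }
        )
    return pd.DataFrame(rows, columns=["term", "chisq", "df", "p"])


def fit_speed_vs_angle(peaks: pd.DataFrame) -> ModelFit:
    """Absolute peak height against the stimulus' angular screen position.

    During-stimulus peaks only.  With several conditions present the model
    is ``|height| ~ angle * condition`` (testing whether the speed-angle
    coupling differs between stimulus pairs); the subject enters as a
    random intercept.
    """
    df = peaks.loc[
        (peaks["period"] == "during") & peaks["stimulus_angle_deg"].notna()
    ].copy()
    if df.empty:
        raise DesignError("no during-stimulus peaks with a stimulus angle")
    _require_subjects(df)
    if df["condition"].nunique() > 1:
        formula = "abs_height_deg_s ~ stimulus_angle_deg * C(condition)"
    else:
        formula = "abs_height_deg_s ~ stimulus_angle_deg"
    return _fit_mixed(formula, df, "speed_vs_angle")


def fit_preference(peaks: pd.DataFrame) -> ModelFit:
    """Signed (preference-coded) peak height by condition and presence.

    Positive values are turns toward the more-biological member of the
    pair; ``period`` distinguishes stimulus-visible from between-stimulus
    sections.
    """
    df = peaks.loc[peaks["period"].isin(PERIODS)].copy()
    if df.empty:
        raise DesignError("no during/between peaks to fit")
    _require_subjects(df)
    n_cond = df["condition"].nunique()
    n_per = df["period"].nunique()
    if n_cond > 1 and n_per > 1:
        formula = "height_deg_s ~ C(condition) * C(period)"
    elif n_cond > 1:
        formula = "height_deg_s ~ C(condition)"
    elif n_per > 1:
        formula = "height_deg_s ~ C(period)"
    else:
        formula = "height_deg_s ~ 1"
    return _fit_mixed(formula, df, "signed_preference")


def posthoc(fit: ModelFit, peaks: pd.DataFrame, adjust: str = "sidak") -> pd.DataFrame:
    """Estimated marginal mean of each condition-by-period cell, tested vs 0.

    The family-wise adjustment for this means-versus-zero family follows
    the multiplicity correction emmeans applies in the same situation
    (Sidak); ``adjust='none'`` disables it.  A single-cell family is
    returned unadjusted.  Raises on empty cells (rank-deficient design).
    """
    df = peaks.loc[peaks["period"].isin(PERIODS)]
    conditions = sorted(df["condition"].unique())
    periods = [p for p in PERIODS if p in set(df["period"])]
    cells = [(c, p) for c in conditions for p in periods]
    counts = df.groupby(["condition", "period"], observed=True).size()
    empty = [cell for cell in cells if cell not in counts.index]
    if empty:
        raise DesignError(f"empty design cells: {empty}")

    design_info = fit.result.model.data.design_info
    grid = pd.DataFrame(
        {
            "condition": [c for c, _ in cells],
            "period": [p for _, p in cells],
            "stimulus_angle_deg": 0.0,
            "height_deg_s": 0.0,
            "abs_height_deg_s": 0.0,
        }
    )
    (X,) = patsy.build_design_matrices([design_info], grid)
    X = np.asarray(X)
    beta = fit.result.fe_params.to_numpy()
    cov = np.asarray(fit.result.cov_params())[: len(beta), : len(beta)]
    est = X @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    dof = max(fit.n_obs - len(beta) - fit.n_subjects, 1)
    t = est / se
    p = 2 * scipy.stats.t.sf(np.abs(t), dof)
    k = len(cells)
    if adjust == "sidak" and k > 1:
        p_adj = 1.0 - (1.0 - p) ** k
    elif adjust in ("none",) or k == 1:
        p_adj = p.copy()
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return pd.DataFrame(
        {
            "condition": [c for c, _ in cells],
            "period": [p_ for _, p_ in cells],
            "estimate": est,
            "SE": se,
            "t": t,
            "df": dof,
            "p_adjusted": np.clip(p_adj, 0.0, 1.0),
        }
    )


def baseline_check(peaks: pd.DataFrame) -> pd.DataFrame:
    """During/between preference estimates for the single-stimulus control.

    Filters the ellipse-versus-nothing trials and estimates the mean coded
    height per period (positive = toward the side where the ellipse is or
    was shown).  Empty input yields an empty table; with a single subject
    the model degrades to ordinary least squares.
    """
    df = peaks.loc[
        (peaks["condition"] == "ellipse_vs_nothing") & peaks["period"].isin(PERIODS)
    ].copy()
    cols = ["condition", "period", "estimate", "SE", "t", "df", "p_adjusted"]
    if df.empty:
        return pd.DataFrame(columns=cols)
    if df["subject_id"].nunique() >= 2 and df["period"].nunique() > 1:
        fit = fit_preference(df)
        return posthoc(fit, df)
    # single subject (as in the original control) or single period: plain OLS
    rows = []
    periods = [p for p in PERIODS if p in set(df["period"])]
    k = len(periods)
    for period in periods:
        v = df.loc[df["period"] == period, "height_deg_s"].to_numpy()
        est = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        dof = max(len(v) - 1, 1)
        t = est / se if se and np.isfinite(se) and se > 0 else float("nan")
        p = 2 * scipy.stats.t.sf(abs(t), dof) if np.isfinite(t) else float("nan")
        p_adj = min(1.0, 1.0 - (1.0 - p) ** k) if (k > 1 and np.isfinite(p)) else p
        rows.append(
            {
                "condition": "ellipse_vs_nothing",
                "period": period,
                "estimate": est,
                "SE": se,
                "t": t,
                "df": dof,
                "p_adjusted": p_adj,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def during_preference_contrasts(peaks: pd.DataFrame) -> pd.DataFrame:
    """Convenience: the during-stimulus rows of the post hoc table."""
    fit = fit_preference(peaks)
    table = posthoc(fit, peaks)
    return table.loc[table["period"] == "during"].reset_index(drop=True)
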