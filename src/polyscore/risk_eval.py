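"""PRS performance: per-SD odds ratios, percentile-category ORs, AUC, and
age-at-diagnosis differences.

All case/control fits exclude prediabetes individuals and adjust, by
default, for age, sex, BMI, the first ten genetic PCs, and study (entered
as categorical indicators, omitted when a single study is present). ORs are
reported per control-SD of the standardized score with Wald 95% CIs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import AucResult, EffectEstimate, ScoreSet

DEFAULT_COVARIATES = ("age", "sex", "bmi") + tuple(
    f"pc{i}" for i in range(1, 11)
) + ("study",)

SEPARATION_BOUND = 15.0


def _design_matrix(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design matrix; 'study' (or any object/categorical column)
    expands to indicator columns, dropped entirely when constant."""
    cols = []
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} absent from data")
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            if col.nunique() <= 1:
                continue  # e.g. single study
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            if col.nunique() <= 1:
                continue
            cols.append(col.astype(float))
    if not cols:
        return pd.DataFrame(index=df.index)
    return pd.concat(cols, axis=1)


def _merged_case_control(scores, cohort: pd.DataFrame) -> pd.DataFrame:
    if isinstance(scores, ScoreSet):
        scores = scores.scores
    keep = [
        c
        for c in ("individual_id", "z_score", "percentile_category")
        if c in scores.columns
    ]
    df = cohort.merge(scores[keep], on="individual_id", how="inner")
    return df.loc[df["t2d_status"].isin(["case", "control"])].copy()


def _logit_estimate(y, X: pd.DataFrame, term: str, label: str) -> EffectEstimate:
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    flag = None
    try:
        fit = sm.Logit(np.asarray(y, float), Xc).fit(disp=0, maxiter=200)
    except Exception as exc:
        est = EffectEstimate(label=label, beta=np.nan, se=np.nan,
                             flag=f"fit error: {exc}")
        return est
    if not fit.mle_retvals.get("converged", True):
        flag = "non-convergence"
    elif np.max(np.abs(fit.params)) > SEPARATION_BOUND:
        flag = "possible separation"
    i = list(Xc.columns).index(term)
    return EffectEstimate(
        label=label,
        beta=float(fit.params.iloc[i]),
        se=float(fit.bse.iloc[i]),
        n_cases=int(np.sum(y)),
        n_controls=int(len(y) - np.sum(y)),
        flag=flag,
    )


def fit_t2d_model(
    scores,
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    label: str = "overall",
) -> EffectEstimate:
    """Per-SD log-OR of the standardized score on T2D status.

    Logistic regression of case status on ``z_score`` plus covariates;
    prediabetes individuals are excluded. Separation or non-convergence is
    reported through the estimate's ``flag``.
    """
    df = _merged_case_control(scores, cohort)
    y = (df["t2d_status"] == "case").astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    X = pd.concat([df[["z_score"]], _design_matrix(df, covariates)], axis=1)
    return _logit_estimate(y, X, "z_score", label)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def compute_auc(status, score, model: str = "score") -> AucResult:
    """AUC (probability a random case outranks a random control, ties ½)
    with a DeLong 95% confidence interval.

    ``status`` is 1/True for cases. Rejects single-class input.
    """
    y = np.asarray(status, dtype=bool)
    s = np.asarray(score, dtype=float)
    if y.all() or not y.any():
        raise ValueError("AUC needs both cases and controls")
    x_case, x_ctrl = s[y], s[~y]
    m, n = len(x_case), len(x_ctrl)

    tz = _midrank(np.concatenate([x_case, x_ctrl]))
    tx = _midrank(x_case)
    ty = _midrank(x_ctrl)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return AucResult(auc=float(auc), ci_low=lo, ci_high=hi, model=model)


def auc_with_base_model(
    scores,
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
) -> dict:
    """AUCs of base, base+PRS, and PRS-alone logistic models, with ΔAUC.

    AUCs are in-sample, computed on each model's fitted probabilities.
    Returns ``{"base": AucResult, "base_plus_prs": AucResult,
    "prs_alone": AucResult, "delta_auc": float}``.
    """
    df = _merged_case_control(scores, cohort)
    y = (df["t2d_status"] == "case").astype(int).to_numpy()
    base_X = _design_matrix(df, covariates)
    full_X = pd.concat([df[["z_score"]], base_X], axis=1)

    out = {}
    for name, X in (
        ("base", base_X),
        ("base_plus_prs", full_X),
        ("prs_alone", df[["z_score"]]),
    ):
        Xc = sm.add_constant(X.astype(float), has_constant="add")
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        out[name] = compute_auc(y, fit.predict(Xc), model=name)
    out["delta_auc"] = out["base_plus_prs"].auc - out["base"].auc
    return out


def category_or(
    scores,
    cohort: pd.DataFrame,
    reference: str = "40-60%",
    covariates=DEFAULT_COVARIATES,
) -> list[EffectEstimate]:
    """Odds ratio of each percentile category versus the reference.

    One logistic model with category indicators plus covariates; categories
    with an empty case or control cell are flagged (beta = NaN) and left
    out of the model — no continuity correction is applied.
    """
    df = _merged_case_control(scores, cohort)
    if "percentile_category" not in df.columns:
        raise ValueError("scores lack percentile_category; assign categories first")
    df["percentile_category"] = df["percentile_category"].astype(str)
    cats = [c for c in df["percentile_category"].unique()]
    if reference not in cats:
        raise ValueError(f"reference category {reference!r} is empty")
    ref_df = df.loc[df["percentile_category"] == reference]
    if (ref_df["t2d_status"] == "case").sum() == 0 or (
        ref_df["t2d_status"] == "control"
    ).sum() == 0:
        raise ValueError("reference category lacks cases or controls")

    flagged, usable = [], []
    for cat in sorted(set(cats) - {reference}):
        sub = df.loc[df["percentile_category"] == cat, "t2d_status"]
        if (sub == "case").sum() == 0 or (sub == "control").sum() == 0:
            flagged.append(
                EffectEstimate(
                    label=cat, beta=np.nan, se=np.nan,
                    n_cases=int((sub == "case").sum()),
                    n_controls=int((sub == "control").sum()),
                    flag="zero cell",
                )
            )
        else:
            usable.append(cat)

    model_df = df.loc[df["percentile_category"].isin(usable + [reference])]
    y = (model_df["t2d_status"] == "case").astype(int).to_numpy()
    dummies = pd.get_dummies(model_df["percentile_category"], dtype=float)[usable]
    X = pd.concat([dummies, _design_matrix(model_df, covariates)], axis=1)
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)

    results = []
    for cat in usable:
        i = list(Xc.columns).index(cat)
        sub = model_df.loc[model_df["percentile_category"] == cat, "t2d_status"]
        results.append(
            EffectEstimate(
                label=cat,
                beta=float(fit.params.iloc[i]),
                se=float(fit.bse.iloc[i]),
                n_cases=int((sub == "case").sum()),
                n_controls=int((sub == "control").sum()),
                flag=None if fit.mle_retvals.get("converged", True)
                else "non-convergence",
            )
        )
    results.extend(flagged)
    results.sort(key=lambda e: e.label)
    return results


def age_at_dx_by_category(
    cases: pd.DataFrame,
    reference: str = "0-10%",
    category_col: str = "percentile_category",
    age_col: str = "age_at_diagnosis",
) -> list[EffectEstimate]:
    """Mean difference in age at diagnosis (years) versus the reference decile.

    Case-only linear regression of age at diagnosis on percentile-category
    indicators; each coefficient is the mean difference in years relative to
    the reference category.
    """
    df = cases.dropna(subset=[age_col]).copy()
    df[category_col] = df[category_col].astype(str)
    cats = sorted(df[category_col].unique())
    if reference not in cats:
        raise ValueError(f"reference category {reference!r} has no cases")
    if len(cats) < 2:
        raise ValueError("need at least two categories with cases")
    others = [c for c in cats if c != reference]
    dummies = pd.get_dummies(df[category_col], dtype=float)[others]
    Xc = sm.add_constant(dummies, has_constant="add")
    fit = sm.OLS(df[age_col].astype(float), Xc).fit()
    out = []
    for cat in others:
        i = list(Xc.columns).index(cat)
        out.append(
            EffectEstimate(
                label=cat,
                beta=float(fit.params.iloc[i]),
                se=float(fit.bse.iloc[i]),
                n_cases=int((df[category_col] == cat).sum()),
                is_logistic=False,
            )
        )
    return out
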