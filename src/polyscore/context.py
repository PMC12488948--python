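"""Context-dependent PRS effects: stratified ORs, Cochran's Q heterogeneity,
PRS×context interaction tests, and PRS–trait associations.

A context variable (age group, sex, hypertension, obesity, …) splits the
cohort into strata; the per-SD PRS effect is estimated within each stratum
and heterogeneity across strata is assessed with Cochran's Q (with the
DerSimonian–Laird τ² and the I² share reported descriptively). An
alternative, fit on the pooled data, adds a PRS×context interaction term and
compares nested models with a likelihood ratio test. Trait associations are
per-SD effects of the score on quantitative (linear) or binary (logistic)
traits within a T2D-status subgroup, with a Bonferroni flag at
0.05 / number-of-traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import EffectEstimate, HeterogeneityResult
from .risk_eval import (
    DEFAULT_COVARIATES,
    _design_matrix,
    _logit_estimate,
    _merged_case_control,
    compute_auc,
)

#: Strata below this case/control size are flagged (mirrors the
#: meta-analysis eligibility rule of 100 cases and 100 controls).
MIN_STRATUM_CASES = 100
MIN_STRATUM_CONTROLS = 100


@dataclass
class ContextSpec:
    """How to stratify on one context variable.

    ``cut_points`` turns a numeric column into ordered strata (half-open
    intervals); when absent, the column's values are used as categorical
    stratum labels. ``drop_covariates`` removes covariates that coincide
    with the context (e.g. sex in sex-stratified analyses).
    """

    variable: str
    cut_points: tuple = ()
    labels: tuple = ()
    drop_covariates: tuple = ()

    def strata(self, values: pd.Series) -> pd.Series:
        v = values
        if self.cut_points:
            edges = [-np.inf, *self.cut_points, np.inf]
            labels = self.labels or [
                f"{lo}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])
            ]
            return pd.cut(v.astype(float), bins=edges, labels=labels, right=False)
        return v.astype(str).where(v.notna())


#: Default stratifications: age and BMI cut points mirror the usual
#: epidemiological groupings; sex strata drop the sex covariate.
DEFAULT_CONTEXT_SPECS = (
    ContextSpec("age", cut_points=(50.0, 60.0, 70.0),
                labels=("<=50", "50-60", "60-70", ">70")),
    ContextSpec("sex", drop_covariates=("sex",)),
    ContextSpec("bmi", cut_points=(25.0, 30.0),
                labels=("non-overweight", "overweight", "obese")),
)


def stratified_estimates(
    scores,
    cohort: pd.DataFrame,
    spec: ContextSpec,
    covariates=DEFAULT_COVARIATES,
) -> list[EffectEstimate]:
    """Per-SD PRS effect within each stratum of a context variable.

    Covariates named in ``spec.drop_covariates`` are excluded (e.g. sex in
    sex strata). Strata smaller than 100 cases + 100 controls are flagged
    ``small stratum``; strata with an empty class are flagged and skipped.
    """
    if spec.variable not in cohort.columns:
        raise ValueError(f"context variable {spec.variable!r} absent from cohort")
    covs = tuple(c for c in covariates if c not in spec.drop_covariates)
    df = _merged_case_control(scores, cohort)
    strata = spec.strata(df[spec.variable])

    out: list[EffectEstimate] = []
    observed = [s for s in strata.dropna().unique()]
    if hasattr(strata, "cat"):
        observed = [s for s in strata.cat.categories if s in set(observed)]
    else:
        observed = sorted(observed)
    if len(observed) < 2:
        raise ValueError(f"context {spec.variable!r} has fewer than 2 strata")
    for label in observed:
        sub = df.loc[strata == label]
        y = (sub["t2d_status"] == "case").astype(int)
        n_case, n_ctrl = int(y.sum()), int(len(y) - y.sum())
        if n_case == 0 or n_ctrl == 0:
            out.append(
                EffectEstimate(
                    label=f"{spec.variable}={label}", beta=np.nan, se=np.nan,
                    n_cases=n_case, n_controls=n_ctrl, flag="empty class",
                )
            )
            continue
        X = pd.concat([sub[["z_score"]], _design_matrix(sub, covs)], axis=1)
        est = _logit_estimate(y.to_numpy(), X, "z_score", f"{spec.variable}={label}")
        if est.flag is None and (
            n_case < MIN_STRATUM_CASES or n_ctrl < MIN_STRATUM_CONTROLS
        ):
            est.flag = "small stratum"
        out.append(est)
    return out


def cochran_q(estimates) -> HeterogeneityResult:
    """Cochran's Q across k estimates with DerSimonian–Laird τ² and I².

    Weights are inverse-variance, w_i = 1/se_i²; Q = Σ w_i (β_i − β̄)² is
    referred to a chi-square with k−1 df. τ² = max(0, (Q − df) /
    (Σw − Σw²/Σw)) and I² = max(0, (Q − df)/Q)·100 (0 when Q = 0).
    """
    if isinstance(estimates, pd.DataFrame):
        betas = estimates["beta"].to_numpy(float)
        ses = estimates["se"].to_numpy(float)
    else:
        betas = np.array([e.beta for e in estimates], dtype=float)
        ses = np.array([e.se for e in estimates], dtype=float)
    finite = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
    betas, ses = betas[finite], ses[finite]
    k = len(betas)
    if k < 2:
        raise ValueError("Cochran's Q needs at least 2 estimates with finite SEs")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = float(max(0.0, (q - df) / denom)) if denom > 0 else 0.0
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p=p, tau2=tau2, i2=i2)


def interaction_lrt(
    scores,
    cohort: pd.DataFrame,
    spec: ContextSpec,
    covariates=DEFAULT_COVARIATES,
) -> dict:
    """Likelihood ratio test for a PRS×context interaction.

    The reduced model carries the PRS, the context main effect(s), and the
    covariates; the full model adds PRS×context term(s). LRT =
    2(ℓ_full − ℓ_reduced) on df = number of interaction terms.

    Returns ``{"gamma": …, "gamma_se": …, "lrt": …, "df": …, "p": …,
    "converged": …}`` where gamma is the first interaction coefficient.
    """
    if spec.variable not in cohort.columns:
        raise ValueError(f"context variable {spec.variable!r} absent from cohort")
    covs = tuple(c for c in covariates if c not in spec.drop_covariates)
    df_cc = _merged_case_control(scores, cohort)
    strata = spec.strata(df_cc[spec.variable])
    keep = strata.notna()
    df_cc, strata = df_cc.loc[keep], strata[keep]
    levels = (
        [s for s in strata.cat.categories if s in set(strata.dropna())]
        if hasattr(strata, "cat")
        else sorted(strata.unique())
    )
    if len(levels) < 2:
        raise ValueError(f"context {spec.variable!r} does not vary")

    main = pd.get_dummies(
        pd.Categorical(strata, categories=levels), drop_first=True, dtype=float
    )
    main.columns = [f"{spec.variable}={c}" for c in main.columns]
    main.index = df_cc.index
    inter = main.mul(df_cc["z_score"], axis=0)
    inter.columns = [f"z_score:{c}" for c in main.columns]

    y = (df_cc["t2d_status"] == "case").astype(int).to_numpy()
    base = pd.concat(
        [df_cc[["z_score"]], main, _design_matrix(df_cc, covs)], axis=1
    )
    full = pd.concat([base, inter], axis=1)
    fit_r = sm.Logit(y, sm.add_constant(base.astype(float))).fit(disp=0, maxiter=200)
    fit_f = sm.Logit(y, sm.add_constant(full.astype(float))).fit(disp=0, maxiter=200)
    converged = fit_r.mle_retvals.get("converged", True) and fit_f.mle_retvals.get(
        "converged", True
    )
    df_lrt = len(inter.columns)
    if df_lrt == 0:
        raise ValueError("no interaction terms (context constant after encoding)")
    lrt = float(2.0 * (fit_f.llf - fit_r.llf))
    p = float(stats.chi2.sf(max(lrt, 0.0), df_lrt))
    gname = inter.columns[0]
    i = list(sm.add_constant(full.astype(float)).columns).index(gname)
    return {
        "gamma": float(fit_f.params.iloc[i]),
        "gamma_se": float(fit_f.bse.iloc[i]),
        "lrt": lrt,
        "df": df_lrt,
        "p": p,
        "converged": bool(converged),
    }


@dataclass
class TraitSpec:
    """One trait to associate with the score."""

    name: str
    kind: str = "continuous"  # or "binary"
    log_transform: bool = False


def associate_traits(
    scores,
    cohort: pd.DataFrame,
    traits,
    subgroup: str = "controls",
    covariates=DEFAULT_COVARIATES,
    n_traits_for_bonferroni: int = 20,
) -> pd.DataFrame:
    """Per-SD effect of the score on each trait within a T2D-status subgroup.

    Continuous traits use linear regression (beta per SD plus the R²
    increment over the covariate-only model); binary traits use logistic
    regression (OR per SD plus the AUC of the fitted model). Traits may be
    log-transformed first (e.g. triglycerides, HOMA-IR). A result is flagged
    significant when p < 0.05 / ``n_traits_for_bonferroni``. All-missing
    traits are skipped with a note in the ``flag`` column.
    """
    subgroup_status = {"cases": "case", "controls": "control",
                       "prediabetes": "prediabetes"}[subgroup]
    if isinstance(scores, pd.DataFrame):
        sc = scores
    else:
        sc = scores.scores
    df = cohort.merge(sc[["individual_id", "z_score"]], on="individual_id")
    df = df.loc[df["t2d_status"] == subgroup_status].copy()
    threshold = 0.05 / n_traits_for_bonferroni

    rows = []
    for trait in traits:
        if isinstance(trait, str):
            trait = TraitSpec(name=trait)
        if trait.name not in df.columns or df[trait.name].notna().sum() == 0:
            rows.append(
                {"trait": trait.name, "kind": trait.kind, "beta": np.nan,
                 "se": np.nan, "p": np.nan, "n": 0, "significant": False,
                 "flag": "all missing"}
            )
            continue
        sub = df.dropna(subset=[trait.name])
        yv = sub[trait.name].astype(float)
        if trait.log_transform:
            yv = np.log(yv)
        X = pd.concat([sub[["z_score"]], _design_matrix(sub, covariates)], axis=1)
        Xc = sm.add_constant(X.astype(float), has_constant="add")
        extra = {}
        if trait.kind == "continuous":
            fit = sm.OLS(yv, Xc).fit()
            base = sm.add_constant(
                _design_matrix(sub, covariates).astype(float), has_constant="add"
            )
            r2_base = sm.OLS(yv, base).fit().rsquared if base.shape[1] > 1 else 0.0
            extra["r2_increment"] = float(fit.rsquared - r2_base)
            beta, se = float(fit.params["z_score"]), float(fit.bse["z_score"])
            p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan
        elif trait.kind == "binary":
            yb = yv.astype(int)
            fit = sm.Logit(yb, Xc).fit(disp=0, maxiter=200)
            beta, se = float(fit.params["z_score"]), float(fit.bse["z_score"])
            p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan
            extra["or"] = float(np.exp(beta))
            extra["auc"] = compute_auc(yb, fit.predict(Xc)).auc
        else:
            raise ValueError(f"unknown trait kind {trait.kind!r}")
        rows.append(
            {"trait": trait.name, "kind": trait.kind, "beta": beta, "se": se,
             "p": p, "n": int(len(sub)), "significant": bool(p < threshold),
             "flag": None, **extra}
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    return out
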