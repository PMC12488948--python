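"""Cross-validated non-negative linear combination of population-specific PRS.

Several population-specific scores for the same disease can be blended into
a single score by logistic regression of case status on the standardized
scores. Within each population × study cell the cohort is split into k
equal folds; the regression is fit on the k−1 validation folds, any
predictor whose coefficient is negative (or exactly zero) is removed and
the model refit until every remaining coefficient is positive, and the
retained coefficients are used as weights w_k to form the combined score
Σ_k w_k · PRS_k in the held-out testing fold. Each individual is scored
exactly once, by a model that never saw them. The combined score is then
control-standardized like any other score.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import CombinationWeights, ScoreSet
from . import harmonize, score as score_mod

#: |coefficient| beyond which a logistic fit is treated as separated.
SEPARATION_BOUND = 15.0


def _stable_fold_key(individual_id, seed: int) -> str:
    h = hashlib.md5(f"{seed}:{individual_id}".encode()).hexdigest()
    return h


def make_cv_folds(
    cohort: pd.DataFrame, k: int = 3, seed: int = 0
) -> pd.Series:
    """Assign a fold label (0 … k−1) per individual.

    Folds are formed within each population × study cell so every cell is
    evenly represented in every fold; fold sizes within a cell differ by at
    most one. Assignment orders individuals by a seeded hash of their id,
    so it is deterministic and independent of row order.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    for col in ("individual_id", "population", "study"):
        if col not in cohort.columns:
            raise ValueError(f"cohort missing column {col!r}")
    folds = pd.Series(-1, index=cohort.index, dtype=int)
    for key, grp in cohort.groupby(["population", "study"], observed=True):
        if len(grp) < k:
            raise ValueError(
                f"population × study cell {key} has {len(grp)} individuals, "
                f"fewer than k={k}"
            )
        keys = grp["individual_id"].map(lambda i: _stable_fold_key(i, seed))
        order = grp.index[np.argsort(keys.to_numpy())]
        folds.loc[order] = np.arange(len(grp)) % k
    out = folds.copy()
    out.index = cohort["individual_id"].to_numpy()
    out.index.name = "individual_id"
    out.name = "fold"
    return out


def fit_nonneg_weights(
    validation_scores: pd.DataFrame,
    status: pd.Series,
    fold: int = 0,
    drop_all_negative: bool = True,
) -> CombinationWeights:
    """Fit the non-negativity-constrained validation regression.

    Logistic regression of case status (1 = case) on all population-specific
    standardized scores plus an intercept; every predictor whose fitted
    slope is ≤ 0 is removed and the model refit, until all remaining slopes
    are > 0 or no predictors remain. With ``drop_all_negative=False`` only
    the most negative predictor is removed per iteration.

    Non-convergence or apparent separation (|coefficient| > 15) marks the
    fit as failed rather than returning a silently unreliable weight set.
    """
    y = np.asarray(status, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("validation set needs at least one case and one control")
    predictors = list(validation_scores.columns)
    dropped: dict = {}
    n_iter = 0
    weights: dict = {}
    intercept = float("nan")
    converged = True

    while predictors:
        n_iter += 1
        X = sm.add_constant(validation_scores[predictors].to_numpy(float))
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation raises in statsmodels
            return CombinationWeights(
                fold=fold, weights={}, dropped=dropped, intercept=np.nan,
                converged=False, n_iterations=n_iter, failed=True,
                failure_reason=f"fit error: {exc}",
            )
        converged = bool(fit.mle_retvals.get("converged", True))
        coefs = dict(zip(predictors, fit.params[1:]))
        intercept = float(fit.params[0])
        if not converged or np.max(np.abs(fit.params)) > SEPARATION_BOUND:
            return CombinationWeights(
                fold=fold, weights={}, dropped=dropped, intercept=intercept,
                converged=converged, n_iterations=n_iter, failed=True,
                failure_reason="non-convergence or separation",
            )
        negative = [p for p in predictors if coefs[p] <= 0]
        if not negative:
            weights = {p: float(coefs[p]) for p in predictors}
            break
        if not drop_all_negative:
            negative = [min(negative, key=lambda p: coefs[p])]
        for p in negative:
            dropped[p] = "negative_coefficient"
        predictors = [p for p in predictors if p not in negative]

    failed = not weights
    return CombinationWeights(
        fold=fold, weights=weights, dropped=dropped, intercept=intercept,
        converged=converged, n_iterations=n_iter, failed=failed,
        failure_reason="all predictors eliminated" if failed else None,
    )


def linear_combination_score(
    test_scores: pd.DataFrame, weights: CombinationWeights
) -> pd.Series:
    """Combined PRS = Σ_k w_k · PRS_k over the retained populations.

    Populations dropped during fitting contribute zero. A retained weight
    whose score column is absent from ``test_scores`` is an error.
    """
    missing = [p for p in weights.weights if p not in test_scores.columns]
    if missing:
        raise ValueError(f"weights refer to absent score columns: {missing}")
    out = pd.Series(0.0, index=test_scores.index)
    for pop, w in weights.weights.items():
        out = out + w * test_scores[pop].astype(float)
    return out


def cross_validated_combination(
    cohort: pd.DataFrame,
    score_panel: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    group_by=("population",),
) -> tuple[ScoreSet, list[CombinationWeights]]:
    """Three-fold cross-validated combination over a cohort.

    ``score_panel`` is indexed by ``individual_id`` with one column of
    standardized scores per source population. For each fold f, weights are
    fit on the case/control individuals of the other folds and applied to
    fold f, so every individual receives exactly one combined score from a
    model not fit on them. The combined raw scores are then
    control-standardized within ``group_by`` groups.

    Any fold whose validation fit fails halts the pipeline with that fold's
    diagnostics attached to the raised error.
    """
    folds = make_cv_folds(cohort, k=k, seed=seed)
    ids = cohort["individual_id"].to_numpy()
    panel = score_panel.loc[ids]
    status = cohort.set_index("individual_id")["t2d_status"].loc[ids]

    combined = pd.Series(np.nan, index=panel.index)
    all_weights: list[CombinationWeights] = []
    for f in range(k):
        test_mask = folds.loc[ids].to_numpy() == f
        val_mask = ~test_mask
        cc = status[val_mask].isin(["case", "control"]).to_numpy()
        val_scores = panel.loc[val_mask].loc[cc]
        val_y = (status[val_mask][cc] == "case").astype(int)
        w = fit_nonneg_weights(val_scores, val_y, fold=f)
        all_weights.append(w)
        if w.failed and w.failure_reason != "all predictors eliminated":
            raise RuntimeError(
                f"validation fit failed in fold {f}: {w.failure_reason} "
                f"(dropped={w.dropped}, iterations={w.n_iterations})"
            )
        combined.loc[test_mask] = linear_combination_score(
            panel.loc[test_mask], w
        ).to_numpy()

    scoreset = score_mod.standardize_scores(combined, cohort, group_by=group_by)
    return scoreset, all_weights


def multi_source_scores(
    panel,
    weight_tables: list[pd.DataFrame],
    cohort: pd.DataFrame,
    group_by=("population", "study"),
    info_min: float = 0.4,
    eff_n_min: float = 30.0,
) -> pd.DataFrame:
    """Standardized score per individual for each source weight table.

    Runs the full harmonization (quality filters, allele matching), scoring
    and control standardization for every weight table and returns a
    DataFrame indexed by ``individual_id`` with one z-score column per
    ``source_population``. The intermediate standardization groups default
    to population × study, the grouping used when the scores feed the
    cross-validated combination.
    """
    meta = harmonize.filter_variants(panel.variants, info_min, eff_n_min)
    kept_pos = np.flatnonzero(meta["kept"].to_numpy())
    kept_meta = meta.iloc[kept_pos].reset_index(drop=True)
    cols = {}
    for table in weight_tables:
        source = str(table["source_population"].iloc[0])
        matched = harmonize.match_alleles(table, kept_meta)
        # panel_index refers to positions within kept_meta; remap to panel
        usable = matched["excluded_reason"] == "none"
        matched.loc[usable, "panel_index"] = kept_pos[
            matched.loc[usable, "panel_index"].to_numpy(int)
        ]
        raw = score_mod.compute_prs(panel, matched)
        ss = score_mod.standardize_scores(raw, cohort, group_by=group_by)
        cols[source] = ss.scores.set_index("individual_id")["z_score"]
    return pd.DataFrame(cols)
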