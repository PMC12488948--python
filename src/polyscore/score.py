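"""Raw PRS computation and control-anchored standardization.

The polygenic risk score of an individual is the weighted sum of
effect-allele dosages over the harmonized variants. Scores are then put on
a common scale by subtracting the mean and dividing by the sample SD of the
score among *controls* within each group (by default, within each
population), so a one-unit increase in the standardized score is a one
control-SD increase. Percentile categories (0–10 … 90–100%) are cut at the
control distribution's percentiles within the same groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    PERCENTILE_CATEGORIES,
    PERCENTILE_CUTS,
    DosagePanel,
    ScoreSet,
)


def effect_allele_dosage(panel: DosagePanel, matched: pd.DataFrame) -> np.ndarray:
    """Samples × matched-variants matrix of effect-allele dosages.

    Effect dosage is the alternate dosage for ``direct``/``flip``
    orientations and ``2 − alt dosage`` for ``swap``/``swap_flip``. Missing
    dosages are mean-imputed from the panel's per-variant dosage mean
    (matching PLINK's default scoring behavior).
    """
    usable = matched.loc[matched["excluded_reason"] == "none"]
    if len(usable) == 0:
        raise ValueError("no usable matched variants: score undefined")
    idx = usable["panel_index"].to_numpy(int)
    dos = panel.dosages[:, idx].astype(float, copy=True)
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        if np.isnan(col_mean).any():
            raise ValueError("variant with all dosages missing cannot be imputed")
        rows, cols = np.nonzero(np.isnan(dos))
        dos[rows, cols] = col_mean[cols]
    swap = usable["orientation"].isin(["swap", "swap_flip"]).to_numpy()
    dos[:, swap] = 2.0 - dos[:, swap]
    return dos


def compute_prs(panel: DosagePanel, matched: pd.DataFrame) -> pd.Series:
    """Raw PRS per individual: Σ_v w_v · (effect-allele dosage)_iv."""
    usable = matched.loc[matched["excluded_reason"] == "none"]
    dos = effect_allele_dosage(panel, matched)
    weights = usable["effect_weight"].to_numpy(float)
    raw = dos @ weights
    return pd.Series(raw, index=pd.Index(panel.sample_ids, name="individual_id"))


def standardize_scores(
    raw: pd.Series,
    cohort: pd.DataFrame,
    group_by=("population",),
) -> ScoreSet:
    """Standardize raw scores within groups using control mean and SD.

    ``cohort`` must carry ``individual_id``, ``t2d_status`` (``case`` /
    ``control`` / ``prediabetes``), and the grouping columns (plus
    ``population`` and ``study`` for bookkeeping). Cases and prediabetes
    individuals are standardized with their group's *control* parameters
    (sample SD, n−1 denominator). Groups with fewer than two controls or a
    zero control SD are rejected by name.
    """
    if isinstance(group_by, str):
        group_by = (group_by,)
    group_by = tuple(group_by)

    df = cohort.copy()
    if "individual_id" not in df.columns:
        raise ValueError("cohort must carry an individual_id column")
    df = df.set_index("individual_id")
    missing = raw.index.difference(df.index)
    if len(missing):
        raise ValueError(f"{len(missing)} scored individuals absent from cohort")
    df = df.loc[raw.index]
    df["raw_score"] = raw.to_numpy(float)

    params = []
    z = pd.Series(np.nan, index=df.index)
    for key, grp in df.groupby(list(group_by), observed=True, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        ctrl = grp.loc[grp["t2d_status"] == "control", "raw_score"]
        name = ", ".join(f"{c}={v}" for c, v in zip(group_by, key))
        if len(ctrl) < 2:
            raise ValueError(f"group ({name}) has fewer than 2 controls")
        mean = float(ctrl.mean())
        sd = float(ctrl.std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"group ({name}) has zero control score variance")
        z.loc[grp.index] = (grp["raw_score"] - mean) / sd
        params.append(dict(zip(group_by, key), control_mean=mean, control_sd=sd))

    out = df.reset_index()[
        ["individual_id"]
        + [c for c in ("population", "study") if c in df.columns]
        + ["raw_score"]
    ]
    out["z_score"] = z.to_numpy()
    for col in group_by:
        if col not in out.columns:
            out[col] = df[col].to_numpy()
    return ScoreSet(
        scores=out, group_by=group_by, group_params=pd.DataFrame(params)
    )


def assign_percentile_categories(
    scoreset: ScoreSet, cohort: pd.DataFrame | None = None
) -> ScoreSet:
    """Attach percentile categories cut at control z-score percentiles.

    Cut points sit at the 10/20/40/60/80/90th percentiles of the control
    z-score distribution within each standardization group; bins are
    half-open ``[low, high)`` so a tie at a cut point falls in the upper
    bin. ``cohort`` is only needed when the score table itself lacks a
    ``t2d_status`` column.
    """
    df = scoreset.scores.copy()
    if "t2d_status" not in df.columns:
        if cohort is None:
            raise ValueError("need t2d_status (pass the cohort table)")
        status = cohort.set_index("individual_id")["t2d_status"]
        df["t2d_status"] = df["individual_id"].map(status)

    cats = pd.Series(pd.NA, index=df.index, dtype=object)
    for _, grp in df.groupby(list(scoreset.group_by), observed=True):
        ctrl_z = grp.loc[grp["t2d_status"] == "control", "z_score"].to_numpy(float)
        if len(ctrl_z) < len(PERCENTILE_CUTS) + 1:
            raise ValueError("fewer controls than percentile cut points in a group")
        cuts = np.percentile(ctrl_z, PERCENTILE_CUTS)
        idx = np.searchsorted(cuts, grp["z_score"].to_numpy(float), side="right")
        cats.loc[grp.index] = np.asarray(PERCENTILE_CATEGORIES, dtype=object)[idx]

    out = scoreset.scores.copy()
    out["percentile_category"] = pd.Categorical(
        cats, categories=list(PERCENTILE_CATEGORIES), ordered=True
    )
    return ScoreSet(
        scores=out, group_by=scoreset.group_by, group_params=scoreset.group_params
    )
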