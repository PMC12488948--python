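"""Phenome-wide association scan of the PRS over phecode-defined phenotypes.

ICD-9-CM / ICD-10-CM diagnosis records are grouped into phecodes; a person
is a case for a phecode when they carry at least two mapped records
(count = 1 is neither case nor control under the default policy), a control
when they carry none and fall outside any exclusion range of a phecode they
do have. Each phecode with at least ``min_cases`` cases is tested by
logistic regression of case status on the standardized score plus
covariates, with significance at the per-population Bonferroni threshold
0.05 / number-of-phenotypes-tested.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .risk_eval import _design_matrix, SEPARATION_BOUND

VOCABULARIES = ("ICD9CM", "ICD10CM")

PHEWAS_COVARIATES = ("age", "sex", "bmi") + tuple(f"pc{i}" for i in range(1, 11))

MAP_COLUMNS = ("icd_code", "vocabulary", "phecode", "phenotype", "category")


def load_phecode_map(path=None) -> pd.DataFrame:
    """Load a phecode map CSV; default is the synthetic fixture map.

    The bundled map is a small synthetic stand-in covering all 17 disease
    categories; real phecode v1.2 / ICD-10-CM beta maps in the same column
    layout (``icd_code, vocabulary, phecode, phenotype, category[,
    exclusion_low, exclusion_high]``) can be dropped in.
    """
    if path is None:
        ref = resources.files("polyscore.data") / "phecode_map_synthetic.csv"
        with resources.as_file(ref) as p:
            pmap = pd.read_csv(p, dtype={"icd_code": str, "phecode": str})
    else:
        pmap = pd.read_csv(path, dtype={"icd_code": str, "phecode": str})
    missing = [c for c in MAP_COLUMNS if c not in pmap.columns]
    if missing:
        raise ValueError(f"phecode map missing columns: {missing}")
    return pmap


def map_icd_to_phecodes(records: pd.DataFrame, phecode_map: pd.DataFrame):
    """Per-person phecode occurrence counts from raw ICD records.

    ``records`` needs ``person_id, code, vocabulary`` columns. Unmapped
    codes are tallied (returned alongside), not fatal; an unknown vocabulary
    label is an error.

    Returns ``(counts, unmapped)`` where ``counts`` is a DataFrame with
    ``person_id, phecode, count`` rows and ``unmapped`` a Series of unmapped
    code → record count.
    """
    for col in ("person_id", "code", "vocabulary"):
        if col not in records.columns:
            raise ValueError(f"ICD records missing column {col!r}")
    unknown = set(records["vocabulary"]) - set(VOCABULARIES)
    if unknown:
        raise ValueError(f"unknown vocabulary labels: {sorted(unknown)}")
    merged = records.merge(
        phecode_map[["icd_code", "vocabulary", "phecode"]],
        left_on=["code", "vocabulary"],
        right_on=["icd_code", "vocabulary"],
        how="left",
    )
    unmapped_mask = merged["phecode"].isna()
    unmapped = merged.loc[unmapped_mask, "code"].value_counts()
    mapped = merged.loc[~unmapped_mask]
    counts = (
        mapped.groupby(["person_id", "phecode"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts, unmapped


def define_phenome(
    counts: pd.DataFrame,
    person_ids,
    phecode_map: pd.DataFrame | None = None,
    min_code_count: int = 2,
    count_one_as_control: bool = False,
) -> pd.DataFrame:
    """Per-person case/control/excluded status for every phecode.

    A person is a case for a phecode when their record count reaches
    ``min_code_count``; a count of exactly one is excluded (neither case nor
    control) unless ``count_one_as_control``; zero-count persons are
    controls unless the phecode lies within an exclusion range
    (``exclusion_low``–``exclusion_high`` in the map) of some phecode the
    person has.

    Returns a wide DataFrame indexed by person with one column per phecode,
    values in {"case", "control", "excluded"}.
    """
    if (counts["count"] < 0).any():
        raise ValueError("negative phecode counts")
    person_ids = pd.Index(person_ids, name="person_id")
    phecodes = sorted(counts["phecode"].unique())
    wide = (
        counts.pivot_table(
            index="person_id", columns="phecode", values="count", fill_value=0
        )
        .reindex(person_ids, fill_value=0)
        .reindex(columns=phecodes, fill_value=0)
        .astype(int)
    )
    status = pd.DataFrame("control", index=person_ids, columns=phecodes)
    status = status.where(wide < min_code_count, "case")
    if not count_one_as_control and min_code_count > 1:
        status = status.mask((wide >= 1) & (wide < min_code_count), "excluded")

    if phecode_map is not None and {"exclusion_low", "exclusion_high"} <= set(
        phecode_map.columns
    ):
        ranges = (
            phecode_map[["phecode", "exclusion_low", "exclusion_high"]]
            .dropna()
            .drop_duplicates()
        )
        if len(ranges):
            numeric = pd.Series({c: float(c) for c in phecodes})
            has = wide >= min_code_count
            for _, row in ranges.iterrows():
                if row["phecode"] not in has.columns:
                    continue
                within = numeric[
                    (numeric >= float(row["exclusion_low"]))
                    & (numeric <= float(row["exclusion_high"]))
                    & (numeric.index != row["phecode"])
                ].index
                carriers = has[row["phecode"]]
                for code in within:
                    col = status[code]
                    status[code] = col.mask(carriers & (col == "control"), "excluded")
    return status


def run_phewas(
    scores,
    phenome: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates=PHEWAS_COVARIATES,
    min_cases: int = 10,
    phecode_map: pd.DataFrame | None = None,
    label: dict | None = None,
) -> pd.DataFrame:
    """One logistic fit per phecode with at least ``min_cases`` cases.

    Returns a results DataFrame with phecode, counts, beta (log-OR per SD),
    se, p, OR, and a ``flag`` column ('skipped: <10 cases' rows are included
    for the audit trail but carry no estimate). ``label`` adds constant
    columns (e.g. population / biobank).
    """
    sc = scores.scores if hasattr(scores, "scores") else scores
    df = cohort.merge(sc[["individual_id", "z_score"]], on="individual_id")
    df = df.set_index("individual_id")
    common = df.index.intersection(phenome.index)
    if len(common) == 0:
        raise ValueError("phenome and scores share no individuals")
    df = df.loc[common]
    X_common = pd.concat(
        [df[["z_score"]], _design_matrix(df, covariates)], axis=1
    ).astype(float)
    Xc_common = sm.add_constant(X_common, has_constant="add")

    annots = {}
    if phecode_map is not None:
        annots = (
            phecode_map.drop_duplicates("phecode")
            .set_index("phecode")[["phenotype", "category"]]
            .to_dict("index")
        )

    rows = []
    for phecode in phenome.columns:
        st = phenome.loc[common, phecode]
        mask = st != "excluded"
        y = (st[mask] == "case").astype(int)
        n_case, n_ctrl = int(y.sum()), int((~y.astype(bool)).sum())
        base = {
            "phecode": phecode,
            "phenotype": annots.get(phecode, {}).get("phenotype"),
            "category": annots.get(phecode, {}).get("category"),
            "n_cases": n_case,
            "n_controls": n_ctrl,
        }
        if n_case < min_cases:
            rows.append({**base, "beta": np.nan, "se": np.nan, "p": np.nan,
                         "or": np.nan, "flag": f"skipped: <{min_cases} cases"})
            continue
        Xc = Xc_common.loc[mask.index[mask]]
        try:
            fit = sm.Logit(y.to_numpy(), Xc).fit(disp=0, maxiter=100)
            flag = None
            if not fit.mle_retvals.get("converged", True):
                flag = "non-convergence"
            elif np.max(np.abs(fit.params)) > SEPARATION_BOUND:
                flag = "possible separation"
            beta = float(fit.params.iloc[list(Xc.columns).index("z_score")])
            se = float(fit.bse.iloc[list(Xc.columns).index("z_score")])
            p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan
        except Exception as exc:
            beta, se, p, flag = np.nan, np.nan, np.nan, f"fit error: {exc}"
        rows.append({**base, "beta": beta, "se": se, "p": p,
                     "or": float(np.exp(beta)), "flag": flag})
    out = pd.DataFrame(rows)
    if label:
        for k, v in label.items():
            out[k] = v
    return out


def bonferroni_threshold(n_phenotypes: int, alpha: float = 0.05) -> float:
    """Bonferroni-adjusted p-value threshold alpha / n."""
    if n_phenotypes < 1:
        raise ValueError("n_phenotypes must be at least 1")
    return alpha / n_phenotypes


def summarize_phewas(results_by_population: dict, alpha: float = 0.05) -> dict:
    """Counts, percent-significant, category shares, and cross-population
    effect correlations.

    ``results_by_population`` maps population label → results DataFrame from
    :func:`run_phewas`. A phecode counts as tested when it carries an
    estimate; significance is at alpha / n-tested within each population.
    Percentages are recomputed from the emitted counts, to one decimal.
    Cross-population agreement is the Pearson correlation of log-ORs over
    phecodes tested in both populations.
    """
    if not results_by_population:
        raise ValueError("empty result set")
    summary: dict = {"populations": {}, "effect_correlations": {}, "overlap": {}}
    sig_sets = {}
    logor = {}
    for pop, res in results_by_population.items():
        tested = res.loc[res["beta"].notna()]
        if len(tested) == 0:
            raise ValueError(f"no tested phecodes for population {pop!r}")
        thr = bonferroni_threshold(len(tested), alpha)
        sig = tested.loc[tested["p"] < thr]
        pct = round(100.0 * len(sig) / len(tested), 1)
        by_cat = {}
        if "category" in sig.columns and sig["category"].notna().any():
            for cat, n in sig["category"].value_counts().items():
                by_cat[cat] = {
                    "n": int(n),
                    "pct_of_significant": round(100.0 * n / len(sig), 1)
                    if len(sig)
                    else 0.0,
                }
        summary["populations"][pop] = {
            "n_tested": int(len(tested)),
            "n_significant": int(len(sig)),
            "pct_significant": pct,
            "bonferroni_threshold": thr,
            "by_category": by_cat,
        }
        sig_sets[pop] = set(sig["phecode"])
        logor[pop] = tested.set_index("phecode")["beta"]

    pops = list(results_by_population)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            shared = logor[a].index.intersection(logor[b].index)
            if len(shared) >= 2:
                r = float(np.corrcoef(logor[a][shared], logor[b][shared])[0, 1])
            else:
                r = np.nan
            summary["effect_correlations"][f"{a}|{b}"] = r
            summary["overlap"][f"{a}|{b}"] = {
                "both": len(sig_sets[a] & sig_sets[b]),
                f"only_{a}": len(sig_sets[a] - sig_sets[b]),
                f"only_{b}": len(sig_sets[b] - sig_sets[a]),
            }
    return summary
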