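"""Synthetic multi-population, multi-study cohorts with known ground truth.

The generator emulates the data a multi-biobank PRS characterization
consumes: per-population genotype dosages with distinct allele frequencies,
population-specific scoring files (noisy copies of the true per-variant
effects, as population-specific posterior weight files would be) plus one
exact meta file, a phenotype table with ADA-style glycemic classification,
covariates, quantitative traits, and an ICD-coded phenome with a mix of
PRS-linked and null phecodes.

Disease status is logistic in the standardized true score:

    logit P(case) = α_pop + β·z + Σ_c γ_c·z·context_c + covariate terms

where z is the true score standardized by the *control* mean and SD within
each population — the same control-anchored scale the scoring module
produces. Because the control set itself depends on the drawn statuses, the
control moments are solved by fixed-point iteration over shared uniform
draws; α_pop is solved so each population attains the configured baseline
prevalence. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .containers import DosagePanel, complement_allele
from .phewas import load_phecode_map

#: mg/dl per mmol/L of glucose.
MGDL_PER_MMOL = 18.016

# Covariate effects on the T2D log odds (fixed study conditions).
AGE_EFFECT_PER_10Y = 0.3
SEX_EFFECT = 0.25
BMI_EFFECT_PER_5U = 0.3

#: Mean ICD-record count for a person latently affected by a phecode /
#: background rate for unaffected persons (Poisson); the affected rate
#: leaves a visible minority of count-one records to exercise the
#: minimum-count rule.
PHECODE_COUNT_MEAN_AFFECTED = 4.0
PHECODE_COUNT_MEAN_BACKGROUND = 0.02

DEFAULT_PHENOME_SPEC = (
    # (phecode, per-SD log-OR, baseline prevalence): half linked, half null
    ("250.2", float(np.log(2.38)), 0.10),
    ("250.7", float(np.log(2.52)), 0.03),
    ("401.1", float(np.log(1.34)), 0.25),
    ("585.3", float(np.log(1.34)), 0.05),
    ("366.2", float(np.log(1.27)), 0.08),
    ("707.2", float(np.log(1.54)), 0.02),
    ("110.1", 0.0, 0.05),
    ("208", 0.0, 0.04),
    ("318", 0.0, 0.10),
    ("782.3", 0.0, 0.12),
    ("747.1", 0.0, 0.02),
    ("871.3", 0.0, 0.02),
)

DEFAULT_TRAIT_EFFECTS = {"hba1c_trait": 0.034, "fasting_glucose_mmol": 0.030}


@dataclass
class GlycemicMeasurements:
    """One person's glycemic work-up (glucose in mg/dl, HbA1c in percent)."""

    age: float
    fasting_glucose: Optional[float] = None
    random_glucose: Optional[float] = None
    hba1c: Optional[float] = None
    ogtt_2h: Optional[float] = None
    physician_diagnosis: bool = False
    age_at_diagnosis: Optional[float] = None


def mmol_to_mgdl(x):
    return np.asarray(x, float) * MGDL_PER_MMOL


def mgdl_to_mmol(x):
    return np.asarray(x, float) / MGDL_PER_MMOL


def classify_glycemic_status(m: GlycemicMeasurements) -> str:
    """ADA-style classification into case / prediabetes / control / unclassified.

    Case: age ≥ 25 with a physician diagnosis, fasting glucose ≥ 126 mg/dl,
    random glucose ≥ 200 mg/dl, or HbA1c ≥ 6.5%. Prediabetes: not a case,
    age ≥ 18, with fasting 100–125 mg/dl, HbA1c 5.7–6.4%, or a 2-h OGTT of
    140–199 mg/dl. Controls must be ≥ 40 and meet neither definition.
    """
    if m.age is None or np.isnan(m.age):
        raise ValueError("age is required")
    values = [m.fasting_glucose, m.random_glucose, m.hba1c, m.ogtt_2h]
    present = [v for v in values if v is not None and not np.isnan(v)]
    if not present and not m.physician_diagnosis:
        raise ValueError("need at least one measurement or a diagnosis flag")
    if any(v < 0 for v in present) or m.age < 0:
        raise ValueError("measurements and age must be non-negative")

    def _get(v):
        return np.nan if v is None else v

    fg, rg, hba1c, ogtt = map(_get, values)
    is_case = m.age >= 25 and (
        m.physician_diagnosis
        or (fg >= 126)
        or (rg >= 200)
        or (hba1c >= 6.5)
    )
    if is_case:
        return "case"
    is_pre = m.age >= 18 and (
        (100 <= fg < 126) or (5.7 <= hba1c < 6.5) or (140 <= ogtt < 200)
    )
    if is_pre:
        return "prediabetes"
    if m.age >= 40:
        return "control"
    return "unclassified"


def classify_cohort(cohort: pd.DataFrame) -> pd.Series:
    """Vectorized classification of a cohort table (same rules as
    :func:`classify_glycemic_status`); expects the measurement columns
    emitted by :func:`simulate_cohort`."""
    age = cohort["age"].to_numpy(float)
    fg = cohort["fasting_glucose_mgdl"].to_numpy(float)
    rg = cohort["random_glucose_mgdl"].to_numpy(float)
    hba1c = cohort["hba1c_pct"].to_numpy(float)
    ogtt = cohort["ogtt_2h_mgdl"].to_numpy(float)
    dx = cohort["physician_diagnosis"].to_numpy(bool)
    with np.errstate(invalid="ignore"):
        case = (age >= 25) & (dx | (fg >= 126) | (rg >= 200) | (hba1c >= 6.5))
        pre = (
            ~case
            & (age >= 18)
            & (
                ((fg >= 100) & (fg < 126))
                | ((hba1c >= 5.7) & (hba1c < 6.5))
                | ((ogtt >= 140) & (ogtt < 200))
            )
        )
    out = np.where(case, "case", np.where(pre, "prediabetes",
                   np.where(age >= 40, "control", "unclassified")))
    return pd.Series(out, index=cohort.index, name="t2d_status")


@dataclass
class SimConfig:
    """Study conditions for one synthetic multi-biobank cohort."""

    populations: tuple = ("AFR", "ASN", "EUR", "HIS")
    n_per_population: int | dict = 1000
    n_variants: int = 100
    maf_range: tuple | dict = (0.05, 0.5)
    true_beta_prs: float = float(np.log(1.78))
    context_effects: dict = field(default_factory=dict)
    trait_effects: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_EFFECTS))
    trait_sd: float = 0.5
    phenome_spec: tuple = DEFAULT_PHENOME_SPEC
    n_studies: int = 2
    age_at_dx_slope: float = -2.5
    t2d_prevalence: float = 0.28
    prediabetes_rate: float = 0.04
    weight_noise_sd: float = 0.15
    seed: int = 0

    def n_for(self, pop: str) -> int:
        if isinstance(self.n_per_population, dict):
            return int(self.n_per_population[pop])
        return int(self.n_per_population)

    def maf_range_for(self, pop: str) -> tuple:
        if isinstance(self.maf_range, dict):
            return tuple(self.maf_range[pop])
        return tuple(self.maf_range)

    def validate(self) -> "SimConfig":
        if not self.populations:
            raise ValueError("populations must be non-empty")
        for pop in self.populations:
            if self.n_for(pop) < 1:
                raise ValueError(f"n_per_population must be >= 1 (population {pop})")
            lo, hi = self.maf_range_for(pop)
            if not (0 < lo <= hi <= 0.5):
                raise ValueError(
                    f"maf_range for {pop} must lie in (0, 0.5], got ({lo}, {hi})"
                )
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not (0 < self.t2d_prevalence < 1):
            raise ValueError("t2d_prevalence must lie in (0, 1)")
        if not (0 <= self.prediabetes_rate < 1):
            raise ValueError("prediabetes_rate must lie in [0, 1)")
        for code, _, prev in self.phenome_spec:
            if not (0 < prev < 1):
                raise ValueError(
                    f"phenome_spec prevalence for {code} must lie in (0, 1)"
                )
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        return self


def _covariate_lp(cov: pd.DataFrame) -> np.ndarray:
    return (
        AGE_EFFECT_PER_10Y * (cov["age"].to_numpy() - 60.0) / 10.0
        + SEX_EFFECT * cov["sex"].to_numpy()
        + BMI_EFFECT_PER_5U * (cov["bmi"].to_numpy() - 28.0) / 5.0
    )


def _draw_covariates(rng, n: int, pop_index: np.ndarray, config: SimConfig):
    cov = pd.DataFrame(
        {
            "age": rng.uniform(40.0, 80.0, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": np.clip(rng.normal(28.0, 5.0, n), 16.0, 55.0),
        }
    )
    pcs = rng.normal(0.0, 1.0, (n, 10))
    pcs[:, 0] += 0.5 * pop_index  # mild population structure on PC1
    for i in range(10):
        cov[f"pc{i + 1}"] = pcs[:, i]
    cov["study"] = np.array(
        [f"study{j + 1}" for j in rng.integers(0, config.n_studies, n)]
    )
    for ctx in config.context_effects:
        cov[ctx] = rng.integers(0, 2, n).astype(float)
    return cov


def _solve_status(S, pop_index, n_pops, cov, config: SimConfig, rng):
    """Fixed-point solve of control-standardized z and case status."""
    n = len(S)
    u = rng.uniform(size=n)
    pre_flag = rng.uniform(size=n) < config.prediabetes_rate
    cov_lp = _covariate_lp(cov)
    gamma_lp_parts = [
        (g, cov[ctx].to_numpy()) for ctx, g in config.context_effects.items()
    ]

    m = np.zeros(n_pops)
    s = np.ones(n_pops)
    for p in range(n_pops):
        sel = pop_index == p
        m[p] = S[sel].mean()
        s[p] = S[sel].std(ddof=1) if sel.sum() > 1 else 1.0
        if s[p] == 0:
            s[p] = 1.0
    alpha = np.full(n_pops, logit(config.t2d_prevalence))

    case = np.zeros(n, dtype=bool)
    for _ in range(100):
        z = (S - m[pop_index]) / s[pop_index]
        rest = config.true_beta_prs * z + cov_lp
        for g, c in gamma_lp_parts:
            rest = rest + g * z * c
        for p in range(n_pops):
            sel = pop_index == p
            r = rest[sel]

            def excess(a):
                return expit(a + r).mean() - config.t2d_prevalence

            alpha[p] = brentq(excess, -30.0, 30.0)
        new_case = u < expit(alpha[pop_index] + rest)
        m_new, s_new = m.copy(), s.copy()
        for p in range(n_pops):
            ctrl = (pop_index == p) & ~new_case & ~pre_flag
            if ctrl.sum() < 2:
                raise ValueError(
                    f"population {config.populations[p]} has fewer than 2 controls"
                )
            m_new[p] = S[ctrl].mean()
            s_new[p] = S[ctrl].std(ddof=1)
        done = (
            np.array_equal(new_case, case)
            and np.allclose(m_new, m, atol=1e-12)
            and np.allclose(s_new, s, atol=1e-12)
        )
        case, m, s = new_case, m_new, s_new
        if done:
            break
    z = (S - m[pop_index]) / s[pop_index]
    return case, pre_flag, z, alpha


def _measurements(rng, status: np.ndarray, age, z, config: SimConfig):
    """Glycemic measurements consistent with each drawn status."""
    n = len(status)
    fg = rng.uniform(80.0, 99.0, n)
    rg = rng.uniform(80.0, 139.0, n)
    hba1c = rng.uniform(4.8, 5.65, n)
    ogtt = np.full(n, np.nan)
    dx = np.zeros(n, dtype=bool)

    pre = status == "prediabetes"
    fg[pre] = rng.uniform(101.0, 124.0, pre.sum())
    hba1c[pre] = rng.uniform(5.75, 6.35, pre.sum())

    case = status == "case"
    dx[case] = True
    fg[case] = np.clip(rng.normal(150.0, 25.0, case.sum()), 100.0, 400.0)
    rg[case] = np.clip(rng.normal(180.0, 40.0, case.sum()), 100.0, 450.0)
    hba1c[case] = np.clip(rng.normal(7.5, 1.0, case.sum()), 5.0, 14.0)

    age_at_dx = np.full(n, np.nan)
    age_at_dx[case] = np.clip(
        50.0 + config.age_at_dx_slope * z[case]
        + rng.normal(0.0, 6.0, case.sum()),
        26.0,
        None,
    )
    return fg, rg, hba1c, ogtt, dx, age_at_dx


def _phenome_records(rng, ids, z, config: SimConfig, phecode_map: pd.DataFrame):
    """ICD records realizing the configured phenome."""
    codes_by_phecode = {
        ph: grp[["icd_code", "vocabulary"]].to_records(index=False).tolist()
        for ph, grp in phecode_map.groupby("phecode")
    }
    n = len(ids)
    persons, codes, vocabs, dates = [], [], [], []
    latent = {}
    for phecode, beta, prev in config.phenome_spec:
        if phecode not in codes_by_phecode:
            raise ValueError(f"phenome_spec phecode {phecode} absent from map")
        p = expit(logit(prev) + beta * z)
        affected = rng.uniform(size=n) < p
        latent[phecode] = affected
        counts = np.where(
            affected,
            rng.poisson(PHECODE_COUNT_MEAN_AFFECTED, n),
            rng.poisson(PHECODE_COUNT_MEAN_BACKGROUND, n),
        )
        icds = codes_by_phecode[phecode]
        nz = np.nonzero(counts)[0]
        for i in nz:
            for j in range(counts[i]):
                code, vocab = icds[j % len(icds)]
                persons.append(ids[i])
                codes.append(code)
                vocabs.append(vocab)
                dates.append(f"{2010 + (i + j) % 10}-06-15")
    records = pd.DataFrame(
        {"person_id": persons, "code": codes, "vocabulary": vocabs, "date": dates}
    )
    return records, latent


def _weight_tables(rng, variants: pd.DataFrame, w_true: np.ndarray,
                   config: SimConfig):
    """Scoring files in mixed allele orientations: noisy per-population
    copies of the true effects plus one exact meta table."""
    tables = []
    rel_sd = config.weight_noise_sd * (w_true.std() if len(w_true) > 1 else 1.0)
    sources = list(config.populations) + ["meta"]
    for source in sources:
        w = w_true.copy()
        if source != "meta":
            w = w + rng.normal(0.0, rel_sd, len(w))
        orient = rng.uniform(size=len(w))
        eff = variants["alt_allele"].to_numpy(object).copy()
        oth = variants["ref_allele"].to_numpy(object).copy()
        wt = w.copy()
        swap = orient < 0.25
        eff[swap], oth[swap] = oth[swap].copy(), eff[swap].copy()
        wt[swap] = -wt[swap]  # same score up to a constant shift
        flip = (orient >= 0.25) & (orient < 0.5)
        for arr in (eff, oth):
            arr[flip] = [complement_allele(a) for a in arr[flip]]
        tables.append(
            pd.DataFrame(
                {
                    "variant_id": variants["variant_id"],
                    "chrom": variants["chrom"],
                    "pos": variants["pos"],
                    "effect_allele": eff,
                    "other_allele": oth,
                    "effect_weight": wt,
                    "source_population": source,
                }
            )
        )
    return tables


_NONPALINDROMIC_ALT = {"A": ("C", "G"), "C": ("A", "T"), "G": ("A", "T"),
                       "T": ("C", "G")}


def simulate_cohort(config: SimConfig):
    """Generate (DosagePanel, weight tables, cohort table, ICD records, truth).

    ``truth`` carries the generative ground truth (per-variant weights, the
    control-standardized true score ``z``, per-population intercepts, and
    the latent phenome) for parameter-recovery checks. The cohort table's
    ``t2d_status`` is produced by :func:`classify_cohort` from the emitted
    measurements, so classification round-trips by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pops = list(config.populations)
    n_by_pop = [config.n_for(p) for p in pops]
    n = sum(n_by_pop)
    pop_index = np.repeat(np.arange(len(pops)), n_by_pop)
    ids = np.array([f"id{str(i).zfill(6)}" for i in range(n)])

    # variants and genotypes
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, config.n_variants)]
    alt = np.array(
        [
            _NONPALINDROMIC_ALT[r][k]
            for r, k in zip(ref, rng.integers(0, 2, config.n_variants))
        ]
    )
    variants = pd.DataFrame(
        {
            "variant_id": [f"var{j}" for j in range(config.n_variants)],
            "chrom": "1",
            "pos": 1000 * (np.arange(config.n_variants) + 1),
            "ref_allele": ref,
            "alt_allele": alt,
        }
    )
    dosages = np.empty((n, config.n_variants))
    maf_by_pop = {}
    for p, pop in enumerate(pops):
        lo, hi = config.maf_range_for(pop)
        maf = rng.uniform(lo, hi, config.n_variants)
        maf_by_pop[pop] = maf
        sel = pop_index == p
        dosages[sel] = rng.binomial(2, maf, (sel.sum(), config.n_variants))
    alt_freq = dosages.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(alt_freq, 1.0 - alt_freq)
    variants["info"] = rng.uniform(0.85, 1.0, config.n_variants)
    variants["n"] = n
    panel = DosagePanel(dosages=dosages, sample_ids=list(ids), variants=variants)

    w_true = rng.normal(0.0, 0.15, config.n_variants)
    S = dosages @ w_true

    cov = _draw_covariates(rng, n, pop_index, config)
    case, pre_flag, z, alpha = _solve_status(
        S, pop_index, len(pops), cov, config, rng
    )
    status = np.where(case, "case", np.where(pre_flag, "prediabetes", "control"))
    fg, rg, hba1c, ogtt, dx, age_at_dx = _measurements(
        rng, status, cov["age"].to_numpy(), z, config
    )

    cohort = pd.DataFrame({"individual_id": ids, "population": np.array(pops)[pop_index]})
    cohort = pd.concat([cohort, cov], axis=1)
    cohort["fasting_glucose_mgdl"] = fg
    cohort["random_glucose_mgdl"] = rg
    cohort["hba1c_pct"] = hba1c
    cohort["ogtt_2h_mgdl"] = ogtt
    cohort["physician_diagnosis"] = dx
    cohort["age_at_diagnosis"] = age_at_dx
    cohort["t2d_status"] = classify_cohort(cohort)
    for trait, delta in config.trait_effects.items():
        cohort[trait] = delta * z + rng.normal(0.0, config.trait_sd, n)
    cohort["z_true"] = z

    phecode_map = load_phecode_map()
    records, latent = _phenome_records(rng, ids, z, config, phecode_map)
    weight_tables = _weight_tables(rng, variants, w_true, config)

    truth = {
        "weights": w_true,
        "z": pd.Series(z, index=pd.Index(ids, name="individual_id")),
        "alpha_by_population": dict(zip(pops, alpha)),
        "maf_by_population": maf_by_pop,
        "phenome_latent": latent,
    }
    return panel, weight_tables, cohort, records, truth


def simulate_score_cohort(config: SimConfig):
    """Score-level generator: the same phenotype model driven by a true
    score drawn directly as standard normal, skipping genotypes.

    Returns ``(raw_scores, cohort)`` where ``raw_scores`` is indexed by
    individual id. Used where only the phenotype model matters (calibration
    and power studies); the score is the raw input to
    :func:`polyscore.score.standardize_scores`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pops = list(config.populations)
    n_by_pop = [config.n_for(p) for p in pops]
    n = sum(n_by_pop)
    pop_index = np.repeat(np.arange(len(pops)), n_by_pop)
    ids = np.array([f"id{str(i).zfill(6)}" for i in range(n)])

    S = rng.normal(0.0, 1.0, n)
    cov = _draw_covariates(rng, n, pop_index, config)
    case, pre_flag, z, _ = _solve_status(S, pop_index, len(pops), cov, config, rng)
    status = np.where(case, "case", np.where(pre_flag, "prediabetes", "control"))
    fg, rg, hba1c, ogtt, dx, age_at_dx = _measurements(
        rng, status, cov["age"].to_numpy(), z, config
    )
    cohort = pd.DataFrame({"individual_id": ids, "population": np.array(pops)[pop_index]})
    cohort = pd.concat([cohort, cov], axis=1)
    cohort["fasting_glucose_mgdl"] = fg
    cohort["random_glucose_mgdl"] = rg
    cohort["hba1c_pct"] = hba1c
    cohort["ogtt_2h_mgdl"] = ogtt
    cohort["physician_diagnosis"] = dx
    cohort["age_at_diagnosis"] = age_at_dx
    cohort["t2d_status"] = classify_cohort(cohort)
    for trait, delta in config.trait_effects.items():
        cohort[trait] = delta * z + rng.normal(0.0, config.trait_sd, n)
    cohort["z_true"] = z
    raw = pd.Series(S, index=pd.Index(ids, name="individual_id"), name="raw_score")
    return raw, cohort
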