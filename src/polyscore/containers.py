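"""Shared in-memory containers.

Tabular data (weight tables, cohort tables, matched-variant tables,
PheWAS results) travel as :class:`pandas.DataFrame` objects with documented
column contracts; the small dataclasses here wrap the objects that carry
extra structure or derived statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

#: Columns every weight table must carry.
WEIGHT_TABLE_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "effect_weight",
    "source_population",
)

#: Percentile categories of the standardized score, in ascending order.
PERCENTILE_CATEGORIES = (
    "0-10%",
    "10-20%",
    "20-40%",
    "40-60%",
    "60-80%",
    "80-90%",
    "90-100%",
)

#: Control-percentile cut points (in percent) separating the categories.
PERCENTILE_CUTS = (10, 20, 40, 60, 80, 90)

VALID_ALLELES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement_allele(allele: str) -> str:
    """Watson–Crick complement of a single-base allele."""
    try:
        return _COMPLEMENT[allele]
    except KeyError:
        raise ValueError(f"allele must be one of A/C/G/T, got {allele!r}") from None


def validate_weight_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the weight-table column contract and its invariants.

    Returns the table unchanged on success.
    """
    missing = [c for c in WEIGHT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    alleles = set(table["effect_allele"]) | set(table["other_allele"])
    bad = alleles - VALID_ALLELES
    if bad:
        raise ValueError(f"weight table contains non-ACGT alleles: {sorted(bad)}")
    if (table["effect_allele"] == table["other_allele"]).any():
        raise ValueError("effect_allele equals other_allele for some variants")
    if not np.isfinite(table["effect_weight"].to_numpy(float)).all():
        raise ValueError("non-finite effect weights")
    key = table[["chrom", "pos", "effect_allele", "other_allele"]]
    if key.duplicated().any():
        raise ValueError("duplicate (chrom, pos, alleles) rows in weight table")
    return table


@dataclass
class DosagePanel:
    """Samples × variants alternate-allele dosage matrix with variant metadata.

    ``dosages[i, j]`` is the expected alternate-allele count (0–2) of sample
    ``sample_ids[i]`` at variant ``variants.iloc[j]``; ``NaN`` marks a
    missing dosage. ``variants`` carries at least ``variant_id, chrom, pos,
    ref_allele, alt_allele`` and, for quality filtering, ``maf, info, n``.
    Coordinates are 1-based, as in VCF.
    """

    dosages: np.ndarray
    sample_ids: list
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples × variants array")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("dosage rows do not match sample_ids")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns do not match variant metadata rows")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class ScoreSet:
    """Raw and control-standardized scores with their standardization groups.

    ``scores`` has one row per individual with columns ``individual_id,
    population, study, raw_score, z_score`` and, once assigned,
    ``percentile_category``. ``group_params`` records the control mean and
    sample SD used within each standardization group.
    """

    scores: pd.DataFrame
    group_by: tuple
    group_params: pd.DataFrame


@dataclass
class EffectEstimate:
    """A single log-OR (or linear beta) with its Wald summary.

    ``beta`` is on the log-odds scale for logistic fits and in trait units
    for linear fits; OR/CI fields are exponentiated only when
    ``is_logistic`` is true.
    """

    label: str
    beta: float
    se: float
    n_cases: int = 0
    n_controls: int = 0
    is_logistic: bool = True
    flag: Optional[str] = None
    z: float = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        if self.se > 0 and np.isfinite(self.beta):
            self.z = self.beta / self.se
            self.p = 2.0 * stats.norm.sf(abs(self.z))
        else:
            self.z = np.nan
            self.p = np.nan

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(self.beta - 1.96 * self.se)

    @property
    def ci_high(self) -> float:
        return float(self.beta + 1.96 * self.se)

    @property
    def or_ci(self) -> tuple:
        return (float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "beta": self.beta,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "flag": self.flag,
        }
        if self.is_logistic:
            d["or"] = self.or_
            d["or_ci_low"], d["or_ci_high"] = self.or_ci
        else:
            d["ci_low"], d["ci_high"] = self.ci_low, self.ci_high
        return d


def estimates_to_frame(estimates: list) -> pd.DataFrame:
    """Long results table from a list of :class:`EffectEstimate`."""
    return pd.DataFrame([e.to_dict() for e in estimates])


@dataclass
class AucResult:
    """Area under the ROC curve with a DeLong 95% CI."""

    auc: float
    ci_low: float
    ci_high: float
    model: str = "score"

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC outside [0, 1]: {self.auc}")


@dataclass
class HeterogeneityResult:
    """Cochran's Q with DerSimonian–Laird τ² and the I² share (percent)."""

    q: float
    df: int
    p: float
    tau2: float
    i2: float


@dataclass
class MetaEstimate:
    """Inverse-variance fixed-effect pooled estimate."""

    beta: float
    se: float
    z: float
    p: float
    k: int
    het: Optional[HeterogeneityResult]
    n_cases: int = 0
    n_controls: int = 0
    single_study_passthrough: bool = False
    notes: tuple = ()

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple:
        return (
            float(np.exp(self.beta - 1.96 * self.se)),
            float(np.exp(self.beta + 1.96 * self.se)),
        )


@dataclass
class CombinationWeights:
    """Retained non-negative combination weights for one validation fit.

    ``weights`` maps source population → w_k (> 0 after elimination);
    ``dropped`` maps removed populations to the reason they were removed.
    """

    fold: int
    weights: dict
    dropped: dict
    intercept: float
    converged: bool
    n_iterations: int
    failed: bool = False
    failure_reason: Optional[str] = None
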