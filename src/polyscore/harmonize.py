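"""Align variant weight tables to a dosage panel and apply quality filters.

Scoring files and genotype panels rarely agree on how a variant is written:
the weight's effect allele may be the panel's REF or ALT, and files lifted
between genome builds may additionally be reported on the opposite strand.
:func:`match_alleles` resolves each weight-table variant against the panel
into one of four orientations (direct, swap, flip, swap_flip) or an
exclusion reason. Quality control follows the imputation-era convention:
variants are dropped when the imputation INFO score is below 0.4 or when the
effective sample size 2·MAF·(1−MAF)·N·INFO falls below 30.

All coordinates are 1-based (VCF convention) in every reader and function
of this module.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import (
    VALID_ALLELES,
    complement_allele,
    validate_weight_table,
)

ORIENTATIONS = ("direct", "swap", "flip", "swap_flip")

#: Exclusion reasons recorded on matched-variant tables.
EXCLUSION_REASONS = ("none", "ambiguous", "unmatched", "low_info", "low_eff_n")


def effective_sample_size(maf, n, info):
    """Effective sample size 2·MAF·(1−MAF)·N·INFO at a variant.

    Accepts scalars or arrays; all inputs are validated against their
    domains (MAF in [0, 1], N ≥ 0, INFO in [0, 1]).
    """
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    info = np.asarray(info, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((maf < 0) | (maf > 1)):
            raise ValueError("maf must lie in [0, 1]")
        if np.any(n < 0):
            raise ValueError("n must be non-negative")
        if np.any((info < 0) | (info > 1)):
            raise ValueError("info must lie in [0, 1]")
    out = 2.0 * maf * (1.0 - maf) * n * info
    return float(out) if out.ndim == 0 else out


def filter_variants(
    panel_meta: pd.DataFrame,
    info_min: float = 0.4,
    eff_n_min: float = 30.0,
) -> pd.DataFrame:
    """Partition variants into kept/excluded by INFO and effective-N rules.

    A variant is kept iff ``info >= info_min`` and its effective sample size
    is ``>= eff_n_min``. Variants with missing MAF, INFO, or N are flagged
    ``missing_meta`` rather than silently kept.

    Returns a copy of ``panel_meta`` with added ``eff_n``, ``kept``, and
    ``exclusion_reason`` columns (reason ``none`` for kept variants; a
    low-INFO variant is reported as ``low_info`` even if it also fails the
    effective-N rule).
    """
    required = ("maf", "info", "n")
    missing_cols = [c for c in required if c not in panel_meta.columns]
    if missing_cols:
        raise ValueError(f"panel metadata missing columns: {missing_cols}")
    out = panel_meta.copy()
    maf = out["maf"].to_numpy(float)
    info = out["info"].to_numpy(float)
    n = out["n"].to_numpy(float)
    missing = np.isnan(maf) | np.isnan(info) | np.isnan(n)

    eff_n = np.full(len(out), np.nan)
    ok = ~missing
    eff_n[ok] = effective_sample_size(maf[ok], n[ok], info[ok])
    out["eff_n"] = eff_n

    reason = np.full(len(out), "none", dtype=object)
    reason[ok & (eff_n < eff_n_min)] = "low_eff_n"
    reason[ok & (info < info_min)] = "low_info"
    reason[missing] = "missing_meta"
    out["exclusion_reason"] = reason
    out["kept"] = reason == "none"
    return out


def apply_strand_mapping(table: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Re-coordinate a weight table using a precomputed build/strand mapping.

    ``mapping`` has columns ``old_chrom, old_pos, new_chrom, new_pos,
    strand``. Where strand is ``-`` both alleles are replaced by their
    complements (the variant landed on the opposite strand in the new
    build); weights are never changed. Variants absent from the mapping are
    dropped with a warning that reports how many were lost.
    """
    validate_weight_table(table)
    for col in ("old_chrom", "old_pos", "new_chrom", "new_pos", "strand"):
        if col not in mapping.columns:
            raise ValueError(f"mapping table missing column {col!r}")
    bad_strand = set(mapping["strand"]) - {"+", "-"}
    if bad_strand:
        raise ValueError(f"strand values must be '+' or '-', got {sorted(bad_strand)}")

    merged = table.merge(
        mapping,
        left_on=["chrom", "pos"],
        right_on=["old_chrom", "old_pos"],
        how="left",
    )
    unmapped = merged["new_pos"].isna()
    if unmapped.any():
        warnings.warn(
            f"{int(unmapped.sum())} weight-table variants absent from the "
            "strand/build mapping were dropped",
            stacklevel=2,
        )
        merged = merged.loc[~unmapped]

    out = merged.copy()
    out["chrom"] = out["new_chrom"].astype(table["chrom"].dtype)
    out["pos"] = out["new_pos"].astype(int)
    minus = out["strand"] == "-"
    out.loc[minus, "effect_allele"] = out.loc[minus, "effect_allele"].map(
        complement_allele
    )
    out.loc[minus, "other_allele"] = out.loc[minus, "other_allele"].map(
        complement_allele
    )
    return out[list(table.columns)].reset_index(drop=True)


def _is_palindromic(a1: str, a2: str) -> bool:
    return complement_allele(a1) == a2


def _orient(effect: str, other: str, ref: str, alt: str):
    """Orientation of a weight pair against a panel REF/ALT pair, or None."""
    if effect == alt and other == ref:
        return "direct"
    if effect == ref and other == alt:
        return "swap"
    ce, co = complement_allele(effect), complement_allele(other)
    if ce == alt and co == ref:
        return "flip"
    if ce == ref and co == alt:
        return "swap_flip"
    return None


def match_alleles(
    table: pd.DataFrame,
    panel_meta: pd.DataFrame,
    ambiguous_policy: str = "exclude",
) -> pd.DataFrame:
    """Match weight-table variants to panel variants by position and alleles.

    Both sides must use 1-based coordinates. For palindromic weight pairs
    (A/T or C/G) strand orientation cannot be inferred from the alleles;
    under the default policy ``"exclude"`` these are removed with reason
    ``ambiguous``, while ``"assume-plus-strand"`` takes the direct/swap
    interpretation.

    Returns one row per weight-table variant with the panel columns
    (``ref_allele``, ``alt_allele``, and the panel's column index
    ``panel_index``), an ``orientation``, and an ``excluded_reason``
    (``none`` for usable variants).
    """
    if ambiguous_policy not in ("exclude", "assume-plus-strand"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    validate_weight_table(table)
    for col in ("chrom", "pos", "ref_allele", "alt_allele"):
        if col not in panel_meta.columns:
            raise ValueError(f"panel metadata missing column {col!r}")
    panel_alleles = set(panel_meta["ref_allele"]) | set(panel_meta["alt_allele"])
    if panel_alleles - VALID_ALLELES:
        raise ValueError("panel contains non-ACGT alleles")
    dup = panel_meta.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        conflicting = panel_meta.loc[dup]
        if conflicting.duplicated(
            subset=["chrom", "pos", "ref_allele", "alt_allele"], keep=False
        ).sum() != dup.sum():
            raise ValueError("duplicate (chrom, pos) with conflicting alleles in panel")

    panel = panel_meta.reset_index(drop=True).copy()
    panel["panel_index"] = np.arange(len(panel))
    merged = table.merge(
        panel[["chrom", "pos", "ref_allele", "alt_allele", "panel_index"]],
        on=["chrom", "pos"],
        how="left",
    )

    orientations = []
    reasons = []
    for row in merged.itertuples(index=False):
        if pd.isna(row.panel_index):
            orientations.append(None)
            reasons.append("unmatched")
            continue
        if _is_palindromic(row.effect_allele, row.other_allele):
            if ambiguous_policy == "exclude":
                orientations.append(None)
                reasons.append("ambiguous")
                continue
            # assume plus strand: only direct/swap interpretations
            if row.effect_allele == row.alt_allele and row.other_allele == row.ref_allele:
                orientations.append("direct")
                reasons.append("none")
            elif row.effect_allele == row.ref_allele and row.other_allele == row.alt_allele:
                orientations.append("swap")
                reasons.append("none")
            else:
                orientations.append(None)
                reasons.append("unmatched")
            continue
        orient = _orient(
            row.effect_allele, row.other_allele, row.ref_allele, row.alt_allele
        )
        if orient is None:
            orientations.append(None)
            reasons.append("unmatched")
        else:
            orientations.append(orient)
            reasons.append("none")

    merged["orientation"] = orientations
    merged["excluded_reason"] = reasons
    merged["panel_index"] = merged["panel_index"].astype("Int64")
    return merged
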