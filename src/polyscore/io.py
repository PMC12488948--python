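"""Readers and writers for the standard interchange formats.

Scoring files follow the PGS-Catalog layout (tab-separated, ``#``-prefixed
header comments, columns ``rsID, chr_name, chr_position, effect_allele,
other_allele, effect_weight``). Dosage panels round-trip through VCF with a
per-sample ``DS`` FORMAT field (read via cyvcf2) or a plain TSV matrix.
Coordinates are 1-based everywhere.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .containers import DosagePanel, validate_weight_table
from .simulate import SimConfig

_PGS_COLS = {
    "rsID": "variant_id",
    "chr_name": "chrom",
    "chr_position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_weight": "effect_weight",
}


def read_scoring_file(path, source_population: str | None = None) -> pd.DataFrame:
    """Read a PGS-Catalog-style scoring file into a weight table.

    ``#`` lines are treated as header comments; a ``# source_population=``
    comment, when present, populates the table's source label unless
    overridden by the argument.
    """
    header_source = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "source_population=" in line:
                header_source = line.split("source_population=")[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chr_name": str})
    missing = [c for c in _PGS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"scoring file missing columns: {missing}")
    table = df.rename(columns=_PGS_COLS)[list(_PGS_COLS.values())]
    table["pos"] = table["pos"].astype(int)
    table["source_population"] = source_population or header_source or "unknown"
    return validate_weight_table(table)


def write_scoring_file(table: pd.DataFrame, path) -> None:
    validate_weight_table(table)
    inverse = {v: k for k, v in _PGS_COLS.items()}
    out = table[list(_PGS_COLS.values())].rename(columns=inverse)
    with open(path, "w") as fh:
        fh.write("# PGS-catalog-style scoring file\n")
        fh.write(
            f"# source_population={table['source_population'].iloc[0]}\n"
        )
        out.to_csv(fh, sep="\t", index=False)


def write_dosage_vcf(panel: DosagePanel, path) -> None:
    """Write the panel as an uncompressed VCF with a DS FORMAT field and
    MAF/INFO/NS entries in the INFO column."""
    v = panel.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,'
                 'Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,'
                 'Description="Imputation quality">\n')
        fh.write('##INFO=<ID=NS,Number=1,Type=Integer,'
                 'Description="Sample count">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, panel.sample_ids))
            + "\n"
        )
        for j, row in enumerate(v.itertuples(index=False)):
            info = f"MAF={row.maf:.6g};INFO={row.info:.6g};NS={int(row.n)}"
            ds = "\t".join(
                "." if np.isnan(d) else f"{d:.3f}" for d in panel.dosages[:, j]
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref_allele}"
                f"\t{row.alt_allele}\t.\tPASS\t{info}\tDS\t{ds}\n"
            )


def read_dosage_vcf(path) -> DosagePanel:
    """Read a dosage VCF (DS FORMAT field) into a DosagePanel via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        ds[ds < 0] = np.nan  # cyvcf2 encodes missing floats as negative fill
        rows.append(ds)
        meta.append(
            {
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref_allele": var.REF,
                "alt_allele": var.ALT[0],
                "maf": var.INFO.get("MAF", np.nan),
                "info": var.INFO.get("INFO", np.nan),
                "n": var.INFO.get("NS", len(samples)),
            }
        )
    if not rows:
        raise ValueError(f"no variants in {path}")
    return DosagePanel(
        dosages=np.column_stack(rows) if rows else np.empty((len(samples), 0)),
        sample_ids=samples,
        variants=pd.DataFrame(meta),
    )


def write_dosage_tsv(panel: DosagePanel, dosage_path, meta_path) -> None:
    df = pd.DataFrame(
        panel.dosages,
        index=pd.Index(panel.sample_ids, name="individual_id"),
        columns=panel.variants["variant_id"],
    )
    df.to_csv(dosage_path, sep="\t")
    panel.variants.to_csv(meta_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, meta_path) -> DosagePanel:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
    if list(df.columns) != list(meta["variant_id"]):
        raise ValueError("dosage columns do not match variant metadata order")
    return DosagePanel(
        dosages=df.to_numpy(float), sample_ids=list(df.index), variants=meta
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_fold_weights(weights, path) -> None:
    """Write per-fold combination weights (list of CombinationWeights) as JSON."""
    import json

    payload = [
        {
            "fold": w.fold,
            "weights": w.weights,
            "dropped": w.dropped,
            "intercept": None if np.isnan(w.intercept) else w.intercept,
            "converged": w.converged,
            "n_iterations": w.n_iterations,
            "failed": w.failed,
            "failure_reason": w.failure_reason,
        }
        for w in weights
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_context_config(path):
    """Load context/trait definitions from YAML.

    Layout::

        contexts:
          - variable: age
            cut_points: [50, 60, 70]
            labels: ["<=50", "50-60", "60-70", ">70"]
          - variable: sex
            drop_covariates: [sex]
        traits:
          - name: triglycerides
            kind: continuous
            log_transform: true

    Returns ``(list of ContextSpec, list of TraitSpec)``.
    """
    from .context import ContextSpec, TraitSpec

    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    contexts = [
        ContextSpec(
            variable=c["variable"],
            cut_points=tuple(c.get("cut_points", ())),
            labels=tuple(c.get("labels", ())),
            drop_covariates=tuple(c.get("drop_covariates", ())),
        )
        for c in d.get("contexts", [])
    ]
    traits = [
        TraitSpec(
            name=t["name"],
            kind=t.get("kind", "continuous"),
            log_transform=bool(t.get("log_transform", False)),
        )
        for t in d.get("traits", [])
    ]
    return contexts, traits


def save_config(config: SimConfig, path) -> None:
    d = asdict(config)
    for key in ("populations", "phenome_spec", "maf_range"):
        if isinstance(d[key], tuple):
            d[key] = [list(x) if isinstance(x, tuple) else x for x in d[key]]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "populations" in d:
        d["populations"] = tuple(d["populations"])
    if "phenome_spec" in d:
        d["phenome_spec"] = tuple(tuple(row) for row in d["phenome_spec"])
    if "maf_range" in d and isinstance(d["maf_range"], list):
        d["maf_range"] = tuple(d["maf_range"])
    return SimConfig(**d).validate()
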