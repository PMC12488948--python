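import numpy as np
import pandas as pd
import pytest

import polyscore as ps


@pytest.fixture(scope="session")
def small_sim():
    """One small end-to-end simulated dataset shared by read-only tests."""
    cfg = ps.SimConfig(n_per_population=400, n_variants=60, seed=11)
    panel, weight_tables, cohort, records, truth = ps.simulate_cohort(cfg)
    return {
        "config": cfg,
        "panel": panel,
        "weight_tables": weight_tables,
        "cohort": cohort,
        "records": records,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_panel(rng, n_samples=12, n_variants=6, missing_rate=0.0):
    """A small random dosage panel with non-palindromic ref/alt pairs."""
    from polyscore.containers import DosagePanel

    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    idx = rng.integers(0, len(pairs), n_variants)
    ref = np.array([pairs[i][0] for i in idx])
    alt = np.array([pairs[i][1] for i in idx])
    dos = rng.uniform(0, 2, (n_samples, n_variants))
    if missing_rate:
        mask = rng.uniform(size=dos.shape) < missing_rate
        dos[mask] = np.nan
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(n_variants)],
            "chrom": "1",
            "pos": 100 * (np.arange(n_variants) + 1),
            "ref_allele": ref,
            "alt_allele": alt,
            "maf": rng.uniform(0.05, 0.5, n_variants),
            "info": rng.uniform(0.8, 1.0, n_variants),
            "n": n_samples,
        }
    )
    return DosagePanel(
        dosages=dos,
        sample_ids=[f"s{i}" for i in range(n_samples)],
        variants=variants,
    )
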