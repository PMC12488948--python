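"""Inverse-variance fixed-effect meta-analysis with heterogeneity statistics.

Study-level estimates are pooled with weights w_i = 1/se_i²; the pooled SE
is 1/√Σw. Pooling is hierarchical: studies are first pooled within each
population, and the population-level estimates (including populations
contributed by a single study, which pass through verbatim) feed the
all-populations estimate. Only analyses with at least 100 cases and 100
controls enter a pooled estimate; ineligible studies are dropped with a
logged reason. τ² (DerSimonian–Laird) and I² are reported descriptively
alongside the fixed-effect pool, via the same Cochran's Q implementation
used for stratified analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EffectEstimate, HeterogeneityResult, MetaEstimate
from .context import cochran_q

MIN_CASES = 100
MIN_CONTROLS = 100


def check_eligibility(
    estimate, min_cases: int = MIN_CASES, min_controls: int = MIN_CONTROLS
):
    """Whether an estimate may enter a meta-analysis.

    Returns ``(eligible, reason)``; missing or zero counts make the estimate
    ineligible with reason ``"missing counts"``.
    """
    n_cases = getattr(estimate, "n_cases", None)
    n_controls = getattr(estimate, "n_controls", None)
    if isinstance(estimate, dict):
        n_cases, n_controls = estimate.get("n_cases"), estimate.get("n_controls")
    if n_cases is None or n_controls is None or (n_cases == 0 and n_controls == 0):
        return False, "missing counts"
    if n_cases < min_cases:
        return False, f"fewer than {min_cases} cases"
    if n_controls < min_controls:
        return False, f"fewer than {min_controls} controls"
    return True, None


def _as_estimate(e) -> EffectEstimate:
    if isinstance(e, EffectEstimate):
        return e
    if isinstance(e, MetaEstimate):
        return EffectEstimate(
            label="pooled", beta=e.beta, se=e.se,
            n_cases=e.n_cases, n_controls=e.n_controls,
        )
    return EffectEstimate(
        label=str(e.get("label", "")), beta=float(e["beta"]), se=float(e["se"]),
        n_cases=int(e.get("n_cases", 0)), n_controls=int(e.get("n_controls", 0)),
    )


def ivw_fixed_effect(estimates) -> MetaEstimate:
    """Pool k ≥ 1 estimates by inverse-variance fixed effect.

    With a single input the estimate passes through verbatim with
    ``single_study_passthrough`` set (no heterogeneity statistics). With
    k ≥ 2, heterogeneity (Q, τ², I²) is computed on the same inputs.
    """
    ests = [_as_estimate(e) for e in estimates]
    ests = [e for e in ests if np.isfinite(e.beta) and np.isfinite(e.se) and e.se > 0]
    if len(ests) == 0:
        raise ValueError("no estimates to pool")
    n_cases = int(sum(e.n_cases for e in ests))
    n_controls = int(sum(e.n_controls for e in ests))
    if len(ests) == 1:
        e = ests[0]
        return MetaEstimate(
            beta=e.beta, se=e.se, z=e.z, p=e.p, k=1, het=None,
            n_cases=e.n_cases, n_controls=e.n_controls,
            single_study_passthrough=True,
        )
    betas = np.array([e.beta for e in ests])
    w = np.array([1.0 / e.se**2 for e in ests])
    pooled = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / se
    p = float(2 * stats.norm.sf(abs(z)))
    het = cochran_q(ests)
    return MetaEstimate(
        beta=pooled, se=se, z=z, p=p, k=len(ests), het=het,
        n_cases=n_cases, n_controls=n_controls,
    )


def hierarchical_meta(
    estimates: pd.DataFrame,
    min_cases: int = MIN_CASES,
    min_controls: int = MIN_CONTROLS,
) -> dict:
    """Two-stage pooling: within populations, then across all populations.

    ``estimates`` has one row per study with columns ``population, study,
    beta, se, n_cases, n_controls``. Stage 1 pools eligible studies within
    each population (a lone study passes through); stage 2 pools the stage-1
    population estimates into the overall estimate. Ineligible studies are
    dropped with a note, never silently.

    Returns ``{"per_population": {pop: MetaEstimate}, "overall":
    MetaEstimate, "notes": [...]}``.
    """
    notes = []
    per_pop: dict = {}
    for pop, grp in estimates.groupby("population", observed=True):
        eligible_rows = []
        for row in grp.to_dict("records"):
            ok, reason = check_eligibility(row, min_cases, min_controls)
            if ok:
                eligible_rows.append(row)
            else:
                notes.append(
                    f"dropped {pop}/{row.get('study', '?')}: {reason}"
                )
        if not eligible_rows:
            notes.append(f"population {pop} has no eligible studies")
            continue
        per_pop[pop] = ivw_fixed_effect(eligible_rows)
    if not per_pop:
        raise ValueError("no eligible estimates at any stage")
    overall = ivw_fixed_effect(list(per_pop.values()))
    overall.notes = tuple(notes)
    return {"per_population": per_pop, "overall": overall, "notes": notes}
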