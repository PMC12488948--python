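"""Context-dependent PRS effects: stratified odds ratios with Cochran's Q
heterogeneity, a PRS x context interaction LRT, and trait associations.

Run:  python examples/03_context_and_traits.py
"""

import polyscore as ps
from polyscore import context, score

# A binary context that truly modifies the PRS effect (gamma = 0.25 on the
# log-odds scale) plus two PRS-linked quantitative traits.
cfg = ps.SimConfig(
    populations=("EUR",), n_per_population=15000, n_studies=1,
    context_effects={"hypertension": 0.25},
    trait_effects={"hba1c_trait": 0.034, "fasting_glucose_mmol": 0.030},
    seed=3,
)
raw, cohort = ps.simulate_score_cohort(cfg)
ss = score.standardize_scores(raw, cohort, group_by=("population",))
covs = ("age", "sex", "bmi")

spec = context.ContextSpec(variable="hypertension")
strata = context.stratified_estimates(ss, cohort, spec, covariates=covs)
for e in strata:
    print(f"{e.label}: OR {e.or_:.2f} ({e.or_ci[0]:.2f}-{e.or_ci[1]:.2f}), "
          f"{e.n_cases} cases / {e.n_controls} controls")

het = context.cochran_q(strata)
print(f"Cochran's Q = {het.q:.2f} (df {het.df}), P_het = {het.p:.2e}, "
      f"I2 = {het.i2:.0f}%, tau2 = {het.tau2:.4f}")

lrt = context.interaction_lrt(ss, cohort, spec, covariates=covs)
print(f"interaction LRT: gamma = {lrt['gamma']:.3f} (truth 0.25), "
      f"p = {lrt['p']:.2e}")

# Trait associations among controls (Bonferroni at 0.05/20 traits).
res = context.associate_traits(
    ss, cohort, traits=["hba1c_trait", "fasting_glucose_mmol"],
    subgroup="controls", covariates=covs,
)
print("\ntrait associations in controls "
      f"(threshold {res.attrs['bonferroni_threshold']:.2e}):")
print(res[["trait", "beta", "se", "p", "significant"]].to_string(index=False))
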