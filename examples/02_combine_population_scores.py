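"""Blend population-specific scores into one PRS by 3-fold cross-validated,
non-negativity-constrained logistic combination.

Run:  python examples/02_combine_population_scores.py
"""

import numpy as np

import polyscore as ps
from polyscore import combine, risk_eval, score

cfg = ps.SimConfig(n_per_population=2000, n_variants=100, seed=7)
panel, weight_tables, cohort, _, truth = ps.simulate_cohort(cfg)

# One standardized score per source scoring file (population-specific noisy
# copies of the true effects). Standardization groups are population x study,
# the grouping used before combination.
pop_tables = [t for t in weight_tables if t["source_population"].iloc[0] != "meta"]
z_panel = combine.multi_source_scores(panel, pop_tables, cohort)
print("score panel columns:", list(z_panel.columns))

# Each fold's validation fit drops any negative-coefficient score and refits;
# retained coefficients weight the combination applied to the held-out fold.
ss, fold_weights = combine.cross_validated_combination(cohort, z_panel, seed=1)
for w in fold_weights:
    kept = {k: round(v, 3) for k, v in w.weights.items()}
    print(f"fold {w.fold}: weights {kept}, dropped {list(w.dropped) or 'none'}")

est = risk_eval.fit_t2d_model(ss, cohort)
print(f"\ncombined score OR per SD: {est.or_:.2f} "
      f"({est.or_ci[0]:.2f}-{est.or_ci[1]:.2f})")

# The combined score tracks the true liability score closely.
merged = ss.scores.set_index("individual_id").join(truth["z"].rename("z_true"))
r = np.corrcoef(merged["z_score"], merged["z_true"])[0, 1]
print(f"correlation with the generative score: r = {r:.3f}")
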