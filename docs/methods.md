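# Methods

## Scoring and standardization

The raw score is the weighted sum of effect-allele dosages over harmonized
variants. Allele harmonization resolves each scoring-file variant against
the panel's REF/ALT pair into one of four orientations — direct (effect =
ALT), swap (effect = REF, effect dosage `2 − ALT dosage`), flip, and
swap+flip (the same two cases after Watson–Crick complementation, for
variants reported on the opposite strand). Palindromic pairs (A/T, C/G)
cannot be oriented from alleles alone and are excluded by default
(`ambiguous_policy="exclude"`); an `assume-plus-strand` policy is available.
Missing dosages are mean-imputed per variant, matching the default behavior
of the standard scoring tools. Variant QC keeps a variant iff its
imputation INFO ≥ 0.4 and its effective sample size
`2·MAF·(1−MAF)·N·INFO ≥ 30`; variants with missing metadata are flagged,
never silently kept.

Scores are standardized by subtracting the mean and dividing by the sample
SD (n−1) of the score **among controls** within each group (default: one
group per population), so "per SD" always means per control-SD. Percentile
categories (0–10, 10–20, 20–40, 40–60, 60–80, 80–90, 90–100%) are cut at
the control z-score percentiles within the same groups, with half-open
bins (a tie at a cut point falls upward). Control-based cut points are a
deliberate choice consistent with control-anchored standardization; a
population-based alternative is a one-line change at the call site since
cut points derive from the score table.

## Cross-validated non-negative combination

Population-specific scores (standardized within population × study) are
blended by logistic regression of case status on all scores plus an
intercept, fit on two of three folds. Every predictor with a non-positive
coefficient is removed — all at once per iteration, matching the plural
phrasing of the rule; one-at-a-time removal is available via
`drop_all_negative=False` — and the model refit until all remaining
coefficients are strictly positive or none remain. Retained coefficients
weight the linear combination applied to the held-out fold, so each
individual is scored exactly once by a model that never saw them. A
coefficient exactly 0 counts as non-positive (strict inequality as the rule
is stated). Folds are assigned within population × study cells by ordering
individuals on a seeded MD5 hash of their id, making assignment
deterministic and row-order independent. Separation is flagged when any
|coefficient| exceeds 15 or the optimizer fails; a failed fold halts the
pipeline with diagnostics rather than imputing. The validation fit uses
intercept + scores only (no covariates), as the combination model is
written; a covariate-adjusted variant can be built from the same pieces.

## Risk evaluation

Per-SD and category ORs come from maximum-likelihood logistic fits
(statsmodels) adjusting for age, sex, BMI, ten PCs, and study (categorical
indicators, dropped automatically when a single study is present);
prediabetes individuals are excluded from case/control fits. CIs use the
Wald 1.96·SE multiplier, p-values the two-sided normal tail. Covariate-free
category ORs therefore equal the 2×2 cross-product ratio exactly. AUC is
the tie-aware rank probability that a random case outranks a random
control; its CI is DeLong's, on the natural scale, as in the pROC default.
AUCs are in-sample (no train/test split), which is optimistic for
prediction but appropriate for the descriptive ΔAUC comparisons made here.
Age-at-diagnosis differences are case-only OLS coefficients on decile
indicators, in years versus the bottom (0–10%) decile.

## Heterogeneity, interactions, traits

Cochran's Q uses inverse-variance weights; τ² is DerSimonian–Laird,
`max(0, (Q − df)/(Σw − Σw²/Σw))` (the estimator is not named by convention
when τ² is reported descriptively; DL is the field default), and
I² = max(0, (Q − df)/Q)·100. Heterogeneity significance is read at an
unadjusted 0.05. The interaction test compares nested logistic models with
and without PRS×context terms by LRT (df = number of interaction terms);
the stratified route and the interaction route are both computed and
labeled distinctly, since they answer subtly different questions. Trait
associations are per-SD effects within a T2D-status subgroup — linear with
an R² increment for continuous traits, logistic with an AUC for binary
ones, optional log transform per trait — flagged at 0.05/20 by default.
Strata below 100 cases + 100 controls are flagged "small stratum",
mirroring the meta-analysis eligibility rule.

## PheWAS

ICD records map to phecodes through a CSV map; the bundled
`phecode_map_synthetic.csv` is a small synthetic stand-in (19 phecodes, all
17 disease categories, both vocabularies) and real phecode v1.2 /
ICD-10-CM-beta maps drop in unchanged. A person is a phecode case at count
≥ 2; count 1 is excluded from both sides by default (the standard
phecode-package behavior; `count_one_as_control=True` restores the liberal
alternative); zero-count persons are controls unless they carry a phecode
whose exclusion range covers the tested code. Scans require ≥ 10 cases,
adjust for age, sex, BMI, and ten PCs, and are summarized with
per-population Bonferroni thresholds, category shares recomputed from
counts, and cross-population Pearson correlations of log-ORs (the log scale
is symmetric; correlating raw ORs would weight risk and protective effects
asymmetrically).

## Meta-analysis

Fixed-effect inverse-variance pooling with τ²/I² reported descriptively
alongside (pooling stays fixed-effect even when heterogeneity is present —
mirrored deliberately). Eligibility (≥ 100 cases and ≥ 100 controls) is
applied per input study before pooling; ineligible studies are dropped with
a logged reason. A lone eligible study passes through verbatim with a flag.
Two-stage pooling (within populations, then across) is algebraically
identical to one-stage pooling, which the tests verify exactly; populations
with no eligible study are dropped from stage 2 with a note.

## Synthetic cohorts

The generator emulates a multi-biobank consortium: per-population variant
frequencies drawn from configurable MAF ranges, hard-call dosages, scoring
files emitted in deliberately mixed allele orientations (direct, swapped
with negated weight, strand-flipped) so the full pipeline exercises
harmonization, per-population noisy weight tables plus one exact meta
table, and multiple study labels per population.

Disease status is logistic — not liability-threshold — so the generative
model coincides with every downstream fit:
`logit P(case) = α_pop + β·z + Σ_c γ_c·z·context_c + covariate terms`, with
fixed covariate effects (0.3 per 10 years of age, 0.25 for male sex, 0.3
per 5 BMI units). The score `z` entering the model is the true raw score
standardized by the **control** mean and SD within each population — the
same scale the scoring module produces — which requires solving the control
moments jointly with the statuses; this is done by fixed-point iteration
over shared uniform draws, with α_pop re-solved by root-finding each
iteration so every population attains the configured baseline prevalence
(default 0.28; prediabetes assigned independently at 0.04). The iteration
terminates when statuses and moments are exactly stable, so a downstream
control standardization of the raw score reproduces the generative `z` to
machine precision and the configured β is exactly the per-SD log-OR the
pipeline estimates. Glycemic measurements (glucose in mg/dl internally,
HbA1c in percent, one conversion constant 18.016 mg/dl per mmol/L) are then
drawn consistently with each status, and the emitted `t2d_status` column is
produced by the classifier itself, so classification round-trips by
construction.

Cases receive an age at diagnosis `50 + slope·z + N(0, 6²)` years; the
default slope of −2.5 years per SD was chosen so the expected gap between
the extreme deciles (mean z-gap ≈ 3.51 for a standard normal) is about
−8.8 years, the magnitude reported for large T2D cohorts. Quantitative
traits are `δ·z + N(0, 0.5²)` with defaults δ = 0.034 (an HbA1c-like trait,
percent units) and 0.030 (fasting glucose, mmol/L). The phenome assigns
each configured phecode a latent Bernoulli phenotype with
`logit p = logit(prev) + logOR·z`, then a Poisson(4.0) record count for
affected persons (background Poisson(0.02)), guaranteeing a visible
minority of count-one persons that exercises the minimum-count rule; the
default phenome is six PRS-linked and six null phecodes.

`simulate_score_cohort` is a score-level variant of the same phenotype
model with the true score drawn directly as standard normal; it is used
where genotypes are irrelevant (calibration and power studies) and keeps
replicated experiments fast.

What the generator does **not** emulate: linkage disequilibrium, admixture
and relatedness, genotyping/imputation error (INFO values are metadata
only), covariate-phenome confounding, secular measurement drift, and
case/control misclassification beyond the count-threshold mechanism.
Passing tests therefore demonstrate the statistical machinery is correct
under its own assumptions, not that a real biobank would show these effect
sizes.

## Numerical choices and problem sizes

Logistic fits use statsmodels' Newton MLE (maxiter 200) with separation
flagged at |coefficient| > 15; flagged estimates are returned with the flag
set, never silently. Ties in AUC count one half; ties at percentile cuts go
to the upper bin. Zero cells in category ORs are flagged without continuity
correction. Replicated experiments in the test suite use cohorts of
4,000–20,000 individuals and 100–200 replicates, sizes at which the Wald
and chi-square asymptotics the checks rely on hold well (logistic Wald
intervals undercover noticeably below a few thousand observations); the
acceptance script uses the same sizes.

## Known limitations

- Age at diagnosis is not constrained to precede the recorded study age
  (clipping would distort the configured slope).
- Contexts are simulated independently of covariates (real obesity
  correlates with BMI); interaction power estimates transfer only
  approximately to correlated contexts.
- In-sample AUCs are optimistic; no train/test split is taken.
- Indels, multi-allelic sites, and chain-file liftover are out of scope;
  build conversion is consumed as a precomputed position/strand mapping.
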