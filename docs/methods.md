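# Methods

This note records the modeling choices behind `neuroage`: what each
stage assumes, the parameters that matter, what the synthetic cohorts do
and do not emulate, and the numerical conventions.

## Feature schema and quality control

The unit of analysis is a participant row with 28 morphometric features
(4 measures x 7 networks), covariates (age in years; sex 0 = male,
1 = female; education 1 = high-school non-graduate; Zung depression
score; Euler number as a surface-reconstruction quality proxy; mean
Euclidean head displacement in mm from the resting-state scan, used as a
motion proxy for the structural acquisition), a scanner label, and
cohort/disorder labels. CSV is the interchange format (RFC 4180, UTF-8,
"." decimal); missing required fields reject the row rather than being
imputed, matching complete-case analysis. The quality-control filter
excludes failed surface reconstructions first and then rows with motion
above 0.4 mm, so the two counts are disjoint.

## Synthetic cohorts

The generator's defaults are the study conditions the pipeline targets:
725 training participants aged 36-100 at two scanners and clinical
groups of 34/72/80 (0/1/2 disorders) aged 35-76.6 on a third scanner.
Each feature follows a linear + quadratic trajectory in age with
plausible scales (thickness ~2.5 mm, sulcal depth ~10 units, area
~1.1e4 mm², volume ~1.4e4 mm³) and per-network multipliers so the 28
trajectories differ; scanner effects are additive offsets in units of
the feature noise SD plus a multiplicative noise-variance factor.

The central device is a latent brain-age deviation per participant:
feature trajectories are evaluated at *effective age* = chronological
age + deviation. In the training cohort the deviation is N(0, 6.5 yr) —
biological heterogeneity that sets the normative model's attainable
cross-validated MAE in the 5-6 year range. In the clinical cohort its
mean is 0 / 3.5 / 6.3 years by disorder burden (the planted dose
effect) with 2 years of residual spread. Encoding the deviation in the
morphometry itself (rather than as bookkeeping) is what makes the dose
effect recoverable by the age model; burden additionally shifts specific
features (thickness down in VIS/VAN/FPN, sulcal depth up in SMN) so
attribution analyses have a network-specific signature to find.

Impairment (NCI) is drawn from
`logit p = intercept + 0.08 * deviation + 0.6 * burden + 0.02 * (zung - 41)`
with intercept −1.8. The per-year coefficient corresponds to an odds
ratio of 1.08 per year of gap; the intercept and direct effect put the
group-wise impairment probabilities near 14/29/45%. A linear-probability
link is available for mediation recovery studies where the planted
indirect effect must be exactly `a x b` on the probability scale. A
limitation: a direct effect linear in burden cannot reproduce a plateau
of impairment risk between one and two disorders.

What the generator does **not** emulate: between-feature correlation
beyond what shared age, deviation, and site terms induce; skewed or
heavy-tailed covariate distributions; site-by-age interactions;
measurement floor/ceiling effects. Passing recovery tests therefore
demonstrates correctness of the estimators under a well-specified
generative model, not robustness to real-data misspecification.

T-score simulation plants impairment by giving a designated subset
≥ 2 domains drawn from N(38, 3), re-drawn until at least two fall at or
below the rule threshold so the planted flag is guaranteed truthful;
with 7 independent domains the rule's intrinsic false-positive rate is
~31%, which real, correlated domains would not show.

## Harmonization

Parametric empirical-Bayes ComBat: per-feature regression on batch
indicators plus the biological design, standardization by pooled
residual variance, normal/inverse-gamma priors estimated by moments
across features, and the standard iterative conditional-posterior
solution (convergence 1e-8). The nonparametric variant and longitudinal
extensions are not implemented. When training and clinical cohorts are
harmonized jointly (the default), a disease indicator (any disorder;
zero for the healthy cohort) joins age and sex in the design so
disorder-related variance is preserved. The implementation agrees with
the reference Bioconductor implementation (`sva::ComBat`) to ~1e-4 —
bounded by that implementation's own iteration tolerance; at matched
tolerance the agreement is ~1e-13.

## Normative age model and bias correction

Kernel: `amplitude * RBF(length-scale) + linear + white noise` on
per-feature standardized inputs with a centered target — the standard
choice for brain-age GP regression, capturing a global trend plus smooth
nonlinearity. Hyperparameters maximize the log marginal likelihood
(L-BFGS, 5 seeded restarts by default); with optimization disabled the
model evaluates the fixed-hyperparameter posterior, which the tests
compare against a dense `k*ᵀ(K+σ²I)⁻¹y` oracle at 1e-8. Jitter starts
at 1e-10 and escalates tenfold to at most 1e-2 if factorization fails.

Cross-validation stratifies folds by age quantiles (stable per-fold
MAE). Bias correction regresses the out-of-fold gap on age and subtracts
the fit, leaving training-set corrected BAG exactly age-orthogonal (OLS
slope zero to machine precision); the training-derived coefficients are
then applied unchanged to clinical data. The alternative (re-estimating
the correction on the test cohort) is deliberately not the default: it
would absorb genuine group effects correlated with age. Per-group
accuracy metrics are computed on corrected predictions.

Because the model is trained on heterogeneous normative data, group-mean
BAG contrasts are mildly attenuated relative to the planted deviations
(regression dilution through feature noise, ~10% at the default noise
level); recovery tests therefore compare contrasts against planted
values within sampling error rather than expecting exact equality.

## Shapley attribution

The value function is interventional: `v(S)` substitutes the
participant's values on coalition `S` into each of the k = 10 training
rows nearest in age (ties broken by participant id) and averages the
model predictions; the baseline is `v(∅)`, the mean prediction of the
reference set. Sampling uses antithetic permutation pairs (default 512
permutations, seeded); marginal contributions along a permutation
telescope, so efficiency holds per draw, and the Monte-Carlo SE treats
each antithetic pair as one independent observation. An exact
enumeration oracle (d ≤ 15) verifies the sampler and the dummy/symmetry
axioms. φ is reported in years, the model's output unit, so feature
contributions read directly as years of predicted age. Exact enumeration
over 2^28 coalitions is infeasible, hence the sampling estimator;
conditional (on-manifold) Shapley values and interaction indices are out
of scope.

## Cohort inference

* **NCI rule**: impaired iff ≥ 2 domains have T ≤ mean − 1.0 SD. The
  boundary is inclusive.
* **Group models**: OLS with sum-to-zero contrasts; the group term's
  Type III F; all three pairwise contrasts with Benjamini–Hochberg
  adjustment. With no covariates and a balanced design this reduces
  exactly to one-way ANOVA (tested).
* **Logistic models**: Newton MLE; focal terms tested by likelihood
  ratio; covariate-adjusted outcome probabilities by marginal
  standardization (G-computation: set every row's exposure, average the
  predictions) with a participant-resampling percentile bootstrap. The
  at-covariate-means variant is intentionally not used — it answers a
  different question for rare outcomes.
* **Factorial HIV x CU models**: binary factors centered (effect
  coding), so each term's test is adjusted for the others; Wald
  chi-square per term in the linear family, LR chi-square from nested
  refits in the logistic family.
* **Mediation**: two-equation path model — mediator equation linear,
  outcome equation linear-probability — so the product-of-coefficients
  indirect effect, the difference of totals, and `total = direct +
  indirect` coincide exactly on every bootstrap draw, and standardized β
  (coefficient x SD(x)/SD(y)) are well-defined. Percentile bootstrap
  over participants (default 2000 draws) gives CIs, SEs, two-sided
  p-values, and the between-contrast indirect difference. A probit
  outcome equation is a possible extension; it would trade the exact
  decomposition for link fidelity.
* **Fisher exact tests**: 2 x C tables are fully enumerated
  (probability-ordering two-sided definition, the r x c convention used
  by R's `fisher.test`, against which the enumeration was verified);
  tables with total > 500 delegate to scipy's network-algorithm
  implementation.
* **Mixed models on signed φ**: random intercept per participant, REML
  estimates; fixed terms tested by LRTs of ML-fitted nested models
  (three-way interaction against the all-two-way model, and so on down
  the hierarchy). Denominator-df approximations (Satterthwaite,
  Kenward–Roger) are deliberately not implemented: they are
  software-specific, and inference here is validated by simulation
  calibration instead. Consequence: the interaction LRT is
  anticonservative in very small cohorts (empirically ~0.09 at 24
  participants, nominal by ~90), so the calibration tests run at sizes
  where the asymptotics hold.
* **FDR**: Benjamini–Hochberg throughout; bootstraps always resample
  participants, never rows of the long attribution table, to respect
  within-participant clustering.

## Problem sizes in the test suite

Tests run the full machinery at reduced scale chosen so each stated
tolerance exceeds ~3x the relevant sampling error: training cohorts of
150-800, clinical groups of 200 for recovery checks, 200-500 replicates
for ordering/calibration rates, bootstrap sizes of 200-1000. The
acceptance script uses a 500-participant training cohort and the default
34/72/80 clinical cohort.
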