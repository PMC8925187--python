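# Methods

`hgclust` re-implements, as a tested pipeline, an analysis linking reconstructed
past mercury (Hg) exposure to clusters of co-occurring neurological symptoms:
variable clustering of ordinal symptom batteries, rule-based reconstruction of
prenatal and childhood Hg exposure from historic biomarker records, latent-variable
structural equation models (SEM) with mediation for ordinal indicators,
longitudinal mixed-effects models (LMEM) of yearly hair Hg, and the supporting
power calculations.  Because the motivating cohort's data are not public, every
stage is exercised and validated on a synthetic cohort generator that plants the
assumed statistical structure and carries its ground truth.

## Synthetic cohorts

The generator (`hgclust.synthetic`) emulates:

- **Ordinal symptoms.** A graded-response-style threshold model: each latent
  symptom factor `f_k` has unit variance; an item with loading λ produces a
  continuous score `λ f_k + N(0, 1−λ²)` cut at four fixed thresholds (default
  −1.2, −0.4, 0.4, 1.2) into five levels.  This matches the polychoric
  assumptions of the downstream CFA/SEM.  Defaults plant 6 clusters of
  37 informative items (sizes 9/7/6/5/5/5, loadings uniform on [0.80, 0.90])
  plus 22 unstructured noise items, for a 59-item battery over 391 participants.
  With the pruning threshold at squared correlation 0.6, ordinal attenuation
  (≈ 0.93 per item) means loadings must exceed ≈ 0.83 for an item's *population*
  item–composite r² to clear the cut; items at 0.80 sit at the boundary and are
  retained or dropped by sampling noise alone.  The defaults keep whole-battery
  recovery reliable at n = 391 while representing that boundary honestly.
- **Exposure history.** Cord blood Hg declines piecewise log-linearly between
  anchors 65.7 µg/L (1970) and 4.48 µg/L (1992); the interior anchors at the
  1976/1987 period breaks (12.0 and 5.0 µg/L) are chosen once to reproduce the
  documented shape — sharp decline to the mid-1970s, slower decline to 1987,
  then a plateau.  Person-level spread is 0.45 log10 decades, consistent with a
  measured within-year range of about two orders of magnitude.  The population
  hair-Hg trend uses anchors 6.6/2.4/1.0/0.81 µg/g with a 0.1 µg/g background
  before the 1962 discharge; a person's childhood exposure is the mean log10
  trend over ages 5–15 plus a person effect, a childhood-fish-consumption shift
  (+0.25 log10) and a residential-school shift (−0.15 log10).
- **Biomarker records.** Sparse yearly hair series: trend + person effect +
  AR(1) observation noise (σ = 0.20 log10, ρ = 0.3; the source data do not
  report within-person autocorrelation, so ρ is exposed as a parameter without
  a fidelity claim), sampled with probability 0.25 per person-year over
  1970–1997; 15% of records are stored as blood values at the 250:1 hair:blood
  ratio so the equivalent-hair conversion is exercised.
- **Mediation.** A diagnosed nervous-system disorder is Bernoulli with log-odds
  linear in standardized childhood exposure (slope 1.0) and feeds the symptom
  factors (standardized effect 0.3), giving the exposure → disorder → symptoms
  chain the SEM layer is meant to detect.
- **Confounding.** Age enters the factors directly (0.25 per SD) and is
  inversely entangled with exposure through birth year — deliberately, since in
  this design age is genuinely ambiguous.  A consequence visible in demo runs:
  the latent-Hg construct correlates with age near −0.9, inflating the
  standardized partial coefficients (with correspondingly huge standard errors)
  when both enter one equation.  The separate-exposure models are much less
  affected.  Null-effect tests therefore zero the covariate effects along with
  the exposure effects.
- **Missingness** is MCAR at 5% on symptoms and selected covariates (the source
  does not describe its mechanism).

What the generator does **not** emulate: seasonality of fish consumption and
sampling, item-specific thresholds, informative missingness, measurement-method
changes over eras.  Passing recovery tests therefore show the algorithms are
correct under the model's own assumptions, not that the original cohort's
estimates are reproduced.

## Variable clustering

Homogeneity of a variable set is the leading eigenvalue of its correlation
matrix — equivalently the sum of squared correlations of members with their
first principal component.  Likert items are treated as numeric 1–5 scores and
standardized, under which the mixed-data PCA criterion reduces to standardized
PCA; a polychoric clustering branch is out of scope.  Agglomeration is greedy:
merge the pair minimizing d(A,B) = H(A) + H(B) − H(A∪B) ≥ 0, ties broken toward
the lexicographically smallest member label.  Correlations use pairwise-complete
observations; composite scores use available-item mean imputation within a
participant × cluster when at least half the items are observed, else missing.
Composites are sign-oriented so higher scores mean more frequent symptoms.
Pruning drops items with item–composite r² < 0.6 and recomputes to a fixpoint,
but never reduces a cluster below two members — such clusters are flagged
degenerate instead; clusters explaining < 50% of their variance are marked not
retained.  Stability is the mean adjusted Rand index (Hubert–Arabie) between
the full-data partition and 60 bootstrap re-clusterings (participants resampled;
one hierarchy per bootstrap sample, cut at every K).  K is selected by maximal
mean ARI with ties broken toward the larger aggregation gap; the full diagnostic
table is always returned for human review, mirroring a selection that was
originally made with several criteria side by side.

## Exposure reconstruction

Biomarker records are reduced to one equivalent-hair value per person-year
(blood × 0.25 µg/g per µg/L — the conventional 250:1 ratio, configurable — and
the yearly maximum kept).  Prenatal and childhood exposures follow a
measurement-first cascade; every value carries a provenance label
(`measured`, `region_year_mean`, `regression`, `cohort_year_mean`,
`era_constant`, `elsewhere_floor`) and the cascade is exhaustive and exclusive.
Era boundaries read the attribution rules half-open: born ≤ 1961 (before the
discharge) → 1.0 µg/L; 1962–1969 → 65.7; ≥ 1993 → 4.48; mother elsewhere →
1.0; ≥ 10 years old in 1962 (born ≤ 1952) → 0.1 µg/g; age 10 after 1990 →
0.81 µg/g.  For 1970–1992 births the region-year mean is used when at least 3
measured births exist that year, otherwise the period regression
(log10 cord on birth year within 1970–76 / 1977–87 / 1988–92; the log scale
follows the global skewness rule, with a linear-scale option).  Attributed
(never measured) cord values are floored at 1.0 µg/L.  Post-1962 childhood
attributions are multiplied by a stratum factor: the ratio of the
(fish consumption × residential school) stratum's geometric-mean measured
childhood Hg to the overall geometric mean — one admissible reading of an
adjustment whose exact formula is not published; it reproduces the direction of
the measured contrasts without inventing coefficients.  A participant with no
childhood measurement and no fish-consumption answer is left unestimated and
flagged.  Estimates are validated against measured values by Spearman rank
correlation.

## Ordinal SEM

The correlation layer estimates polychoric (ordinal–ordinal), polyserial
(ordinal–continuous) and Pearson entries by two-step ML: thresholds from the
margins, then one-dimensional likelihood maximization per pair.  The bivariate
normal CDF is a fresh numpy port of Genz's quadrature (exact to ~1e-15 against
scipy, but vectorized enough to sit in the likelihood loop).  The matrix is
eigenvalue-smoothed to positive semi-definite when needed (logged).  Per-entry
asymptotic variances come from the numerical observed information with
thresholds fixed (threshold uncertainty is ignored — a standard two-step
simplification).

The structural layer fits an acyclic system of standardized linear equations by
DWLS.  Every variable, latent or observed, is scaled to unit variance, so the
estimates are directly the standardized solution, the implied matrix is itself
a correlation matrix, and residual variances are the implicit complements
1 − explained rather than free parameters.  (The common alternative — fix the
first loading at 1 and standardize afterwards — is likelihood-equivalent; the
unit-variance identification removes the rescaling step since the input is
already a correlation matrix.)  A smooth penalty activates when an equation's
systematic variance exceeds 0.98, keeping the optimizer inside the admissible
region; solutions resting on that boundary are flagged as Heywood cases.
A binary ever ≥ 5 µg/g indicator enters through its tetrachoric/polyserial
correlations like any ordinal variable.

Inference uses a sandwich covariance whose middle matrix is the asymptotic
covariance of the correlation estimates, built with the Pearson–Filon
normal-theory formula for the cross-element structure and rescaled so each
element's variance equals its two-step ML estimate.  The reported χ² is the
mean-and-variance (scaled-shifted) adjustment of the DWLS discrepancy — the
raw (N−1)·F statistic under diagonal weights is badly inflated — and the
baseline (independence) model is adjusted the same way.  CFI, TLI (capped at
1), RMSEA with a 90% CI by noncentrality inversion, SRMR, and χ²-based pseudo
AIC/BIC are recomputed from χ², df and N (N−1 is used in the noncentrality
convention).  Measured calibration on correctly specified models: mean χ² ≈ df,
type-I error of the exposure path ≈ 4% at n = 250.

Modification indices are score tests: for each candidate (omitted cross-loading
or indicator residual correlation) the expected drop in the discrepancy from
freeing it, mapped onto the reported χ² scale.  Measured calibration under a
correct model: per-candidate mean ≈ 1.5, P(MI > 3.84) ≈ 12% — adequate for
ranking, slightly liberal as a formal test.  Mediation is decomposed by
exhaustive path enumeration (indirect = product of standardized coefficients
per chain; total = direct + Σ indirect, exact by construction).  Moderation is
a two-group comparison: each group fitted separately, the equality-constrained
multi-group fit reported for df bookkeeping and ΔCFI, with the p-value from the
Wald statistic on the group difference of the constrained path (the raw DWLS χ²
difference is not χ²-scaled under diagonal weights).  SEM power is (i) the
noncentral-χ² RMSEA framework for close/not-close fit with
λ = (N−1)·df·ε², and (ii) Monte-Carlo rejection rates for a target path on a
one-latent test-bed model.

MICE imputation of survey covariates uses chained equations (5 sweeps,
m = 5 by default): predictive mean matching with 5 donors for numeric columns,
logistic draws for binary ones, observed cells untouched, pooling by Rubin's
rules.  The pipeline imputes covariates before SEM; exposure values are never
imputed this way — they come from the attribution cascade.

## Longitudinal mixed models

Participants need ≥ 10 yearly hair values (inclusion counts are reported).
Composite scores are median-split, ties to "below".  The response is log10 hair
Hg (global skewness rule); fixed effects are score group, age at sampling, sex
and sampling year (the latter two centered); the default random structure is a
participant intercept, with the alternative reading of the original's
"age of sampling nested in year of sampling" footnote — year-of-sampling groups
with an age variance component — behind a flag rather than silently chosen.
Model choice diagnostics: REML estimates with Wald CIs, a boundary-corrected
(50:50 χ²₀/χ²₁) likelihood-ratio test against OLS, and ML AIC/BIC.  The group
contrast is also back-transformed to µg/g as a marginal contrast (predict every
row under both group labels, difference of means of 10^fitted) with a
participant-bootstrap percentile CI.  Normality of residuals is checked by a
normal q-q slope and a Shapiro test.  Measured calibration: planted
0.15-log10 differences are recovered (median error < 0.05 at 40 persons ×
12 years); null rejection ≈ 7% at 40 participants (the Wald test uses normal
rather than t critical values, hence slightly liberal at this size).

## Longitudinal power

Under compound symmetry (between-person variance ρ, total 1), the efficient
level-contrast test reduces to a two-sample comparison of person means with
variance (1 + (n−1)ρ)/n, giving
N/group = 2(z₁₋α/2 + z₁₋β)² (1 + (n−1)ρ) / (n δ²), rounded up.  The design
effect (1 + (n−1)ρ)/n makes N non-decreasing in ρ and non-increasing in n.
Because the original effect size of 0.25 is not labelled, both readings are
computed: Cohen's d (δ = 0.25 → total N 96–142 over ρ ∈ {0.1, 0.2}) and
Cohen's f (δ = 0.5 → total N 24–36); the f reading brackets the original's
29–42 range and the grid is reported rather than a single number.  The exact
finite-sample counterpart (noncentral t) and a Monte-Carlo simulation of the
same design agree within 3 percentage points across the (ρ, effect) grid.

## Pipeline

`run_pipeline` executes clustering → exposure → CFA/SEM (both exposure modes
per retained cluster) → LMEM → power, with subsets mirroring the study design:
clustering on all survey participants, SEM on those with ≥ 1 biomarker, LMEM on
those with ≥ 10 yearly values (ordering asserted).  All randomized stages draw
named sub-seeds from one master seed (SHA-256 of "seed:stage", below 2³¹);
outputs are CSV plus a JSON run log keyed by the config hash, and reruns are
byte-identical.  The significance threshold is p ≤ 0.05 throughout and **no
multiple-testing correction is applied**, matching the reproduced analysis
plan; treat marginal pipeline p-values accordingly.

## Problem sizes used in the test suite

Recovery and calibration tests state their replication counts explicitly and
were sized to keep the default suite fast while leaving the acceptance
thresholds untouched: clustering recovery uses 25 cohorts at n = 391; SEM path
recovery 40 fits at n = 250 and type-I calibration 500 null replicates; LMEM
recovery 30 panels of 40 × 12 and null calibration 150 replicates; power
self-consistency a 3 × 3 grid at 1000 Monte-Carlo replicates per cell; the
end-to-end determinism check runs the full 391-participant demo twice.

## Known limitations

- Polychoric variances ignore threshold uncertainty; the Pearson–Filon
  cross-structure is a normal-theory approximation rescaled to ordinal
  variances, not the full ordinal asymptotic covariance.
- The DWLS χ² adjustment targets the first two moments; extreme tails of the
  statistic are approximate, and MI calibration is slightly liberal.
- The LMEM Wald tests use normal critical values; with ~30–40 participants a
  Satterthwaite/Kenward–Roger correction would be less liberal.
- The stratum-ratio covariate adjustment of childhood attributions is one
  admissible reading of an unpublished formula.
- Fixed-effect collinearity between age and reconstructed exposure is inherent
  to the design (exposure is a function of birth cohort); standardized partial
  coefficients from the latent-Hg models should be read jointly with their
  standard errors.
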