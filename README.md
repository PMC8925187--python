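# hgclust

Symptom-cluster and past-mercury-exposure modelling for environmental
epidemiology: a tested, reusable implementation of an analysis pipeline that
links reconstructed historical mercury (Hg) exposure to clusters of
co-occurring neurological symptoms.  It is written for biostatisticians and
environmental-health researchers who have (a) a participant × symptom ordinal
survey table and (b) sparse historical biomarker records (umbilical-cord blood
Hg and yearly blood/hair Hg), and who want the full chain — clustering,
exposure reconstruction, latent-variable modelling, longitudinal modelling —
reproducible from one seeded configuration.

The motivating cohort's data are not public, so the package ships a synthetic
cohort generator that plants the assumed structure (latent symptom factors,
a declining exposure era, a diagnosed-disorder mediator) together with its
ground truth; every stage is validated as a parameter-recovery problem.

## The methods in brief

- **Variable clustering** (`hgclust.varclust`): symptoms are aggregated by
  maximising a homogeneity criterion H = λ₁ of the cluster's correlation matrix
  (the variance captured by its first principal component), merging the pair
  with minimal loss d(A,B) = H(A) + H(B) − H(A∪B).  Each cluster is summarised
  by a composite (first-PC) score; items need squared correlation ≥ 0.6 with
  their composite and clusters ≥ 50% explained variance to survive pruning.
  The number of clusters is guided by a bootstrapped mean adjusted Rand index
  (B = 60) plus the aggregation-gap profile.
- **Exposure reconstruction** (`hgclust.exposure`): one equivalent-hair Hg
  value per person-year (blood converted at 250:1, yearly maximum kept);
  prenatal exposure = cord Hg at birth, childhood exposure = mean hair Hg at
  ages 5–15, each through a measurement-first cascade with era constants
  (1.0 / 65.7 / 4.48 µg/L for cord; 0.1 / 0.81 µg/g for childhood), region-year
  means, period regressions of log10 cord Hg on birth year, and
  fish-consumption × residential-school adjustment factors.  Every value
  carries its provenance.
- **Ordinal SEM** (`hgclust.sem`): polychoric/polyserial correlation matrices
  feed a DWLS fit of standardized acyclic equation systems — symptom clusters
  and (optionally) combined Hg exposure as latent variables, mediation through
  diagnosed nervous-system disorders, covariates, standardized direct/indirect/
  total effect decomposition, scaled-shifted χ² with CFI/TLI/RMSEA/SRMR,
  modification indices, sex-moderation tests, and RMSEA / Monte-Carlo power.
- **Longitudinal mixed models** (`hgclust.lmem`): REML fit of log10 hair Hg on
  the above/below-median composite group with age, sex and year fixed effects
  and a participant random intercept, for participants with ≥ 10 yearly values;
  the group contrast is reported on the log10 and back-transformed µg/g scales.
- **Power** (`hgclust.power`): compound-symmetry longitudinal sample-size
  formula N/group = 2(z₁₋α/2 + z₁₋β)²(1 + (n−1)ρ)/(n δ²) with Monte-Carlo
  cross-checks, reported for both readings (Cohen's d and f) of an effect size
  of 0.25.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Generate a demo cohort (391 participants, 37 informative + 22 noise symptoms,
seed 17) and run the whole pipeline:

```bash
hgclust simulate --out demo --seed 17
hgclust run --config configs/demo.yaml
```

The run log reports the clustering stage as

```
varclust: K=6, n_participants=391, n_retained_symptoms=37
```

i.e. the six planted clusters are found and pruning keeps exactly the 37
informative symptoms while discarding the 22 noise items.  The correlated-
factors CFA of the retained solution (353 participants with complete symptom
links, DWLS on the 37-item polychoric matrix) prints

```
chi2 = 643.60  df = 614  chi2/df = 1.048
CFI = 0.999  TLI = 0.998  RMSEA = 0.012 (90% CI 0.000-0.021)  SRMR = 0.035
```

— the near-unity incremental indices and small RMSEA say the planted
measurement structure is recovered cleanly.  `demo_out/lmem.csv` holds the
longitudinal contrasts (difference in hair Hg between participants above vs
below the median composite score, 33 participants with ≥ 10 yearly values,
357 measurements):

```
cluster  estimate_ugg  ci_low  ci_high  estimate_log10      p
1              0.21    -1.21     1.37           0.045   0.732
2              1.48     0.41     2.48           0.335   0.005
3              0.80    -0.80     1.81           0.170   0.200
4              1.16    -0.13     2.12           0.248   0.044
5              0.54    -0.71     1.78           0.115   0.375
6              0.98     0.02     2.25           0.208   0.082
```

so in this particular synthetic draw, clusters 2 and 4 show significantly
higher past hair Hg in the high-scoring group (≈ 1.5 and 1.2 µg/g), the others
positive but uncertain contrasts.  `hgclust power` prints the sample-size grid:

```
effect_metric  effect_size  delta  rho  n_timepoints  n_per_group  n_total
            d         0.25   0.25  0.1            10           48       96
            d         0.25   0.25  0.2            10           71      142
            f         0.25   0.50  0.1            10           12       24
            f         0.25   0.50  0.2            10           18       36
```

Reruns of `hgclust run` with the same config are byte-identical.

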