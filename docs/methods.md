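# Methods

This note documents the models, procedures and design choices behind
`achburden`. It is written for users who want to understand exactly what the
package computes and what the synthetic-data tests do and do not establish.

## The analysis in one paragraph

Primary-care prescription records are cleaned through a fixed ten-stage
cascade, scored against one or more anticholinergic scales, and summed into a
per-participant cumulative anticholinergic burden (AChB) over a sampling
window. General cognitive ability (g) is the latent factor of a one-factor
confirmatory factor model over a cognitive battery; general white-matter
measures (gFA, gMD) are first principal components of tract-level diffusion
measures. The association battery regresses each standardized outcome on
standardized AChB plus a covariate template, reports standardized
coefficients, and controls the false discovery rate per model family with
confidence intervals tied to the Benjamini–Hochberg critical level.

## Prescription cleaning

The cascade applies, in order: (1) drop records with no drug content
(including names that failed generic-name resolution); (2) drop records with
missing or impossible dates (before 1900, after the extraction date —
default 2016-05-31 — or before the participant's birth year); (3) split
combination products into one record per component; (4) drop records dated
after the participant's death; (5) aggregate to participant-year pairs;
(6) drop years after the supplier's prescription coverage end (default: the
window end); (7) drop each participant's first observed year, which is
unlikely to be completely ascertained; (8) restrict to the sampling window
(default 2000–2015, chosen because earlier years are under-ascertained and
later ones incomplete); (9) drop participants carrying diagnoses that may
affect brain structure or cognition (a configurable flag, since no canonical
list exists); (10) drop records issued within 365 days before the
assessment, or any time after it, to avoid acute drug effects.

Two operationalizations deserve a note:

* **Stage 10.** "Excluding the year preceding assessment" is ambiguous
  between a calendar-year rule and a rolling 365-day rule. The default is
  the strict 365-day record-level rule; `assessment_rule="calendar"`
  switches to dropping whole participant-years at or after the assessment
  year. Participants with no assessment date are excluded at this stage and
  counted in the audit notes rather than raising.
* **Idempotence.** Every stage is an idempotent filter except stage 7, which
  is data-relative: rerunning the cascade on its own output would remove a
  further "first year" each time. This is a property of the published
  cascade design, not an implementation artifact; rerunning with
  `drop_first_year=False` removes nothing.

The audit records `n_in`, `n_removed`, `n_out` per stage, asserts
conservation on every run, and reports stage 3 with a negative removal count
when splitting adds records.

## Burden scoring

A scale maps generic names to potencies in {0.5, 1, 2, 3}; unlisted drugs
score 0 (scales are partial lists by construction). Ophthalmic, otic, nasal
and topical prescriptions score 0 regardless of the drug (negligible
systemic absorption). Scales modified to carry the improbable-action rule
score the flagged drugs 0.5. One prescription is one scoring event; dose and
duration are not modelled because primary-care issue records rarely carry
usable quantity information. ATC classes are the first character (level 1,
anatomical main group) or first four characters (level 3, pharmacological
subgroup) of the drug's unique ATC code; because the assignment is unique,
per-class burden sums reconcile exactly with the totals. Classes prescribed
to fewer than 100 participants (configurable) are excluded from class-level
models. Per-scale polypharmacy is the non-anticholinergic prescription count
(total minus prescriptions scoring > 0 under that scale); a distinct-drug
variant is available behind a flag.

## Latent traits

The cognitive model is a single factor with loadings λ, diagonal residual
variances and residual covariances for designated test pairs:
Σ(θ) = λλᵀ + Θ, factor variance fixed to 1. Estimation minimizes the ML
discrepancy F = log|Σ| + tr(SΣ⁻¹) − log|S| − p over the pairwise-complete
correlation matrix (ML CFA is scale-invariant, so fitting the correlation
matrix loses nothing and makes the standardized solution direct). Residual
variances are log-parametrized with a floor of 1e−6; a solution at the floor
is flagged as a Heywood case. Optimization uses L-BFGS-B with fixed starting
values (loadings 0.5, residual variances 0.5), gradient tolerance 1e−8 and
at most 500 iterations, so fits are bit-reproducible. Fit statistics (χ²,
CFI, TLI, RMSEA, SRMR) use the median pairwise-complete n. The binary
pass/fail indicator is treated as continuous alongside the other tests; a
threshold-link variant is out of scope.

Factor scores use the regression method, ĝ = λᵀΣ⁻¹z evaluated on each
participant's observed indicator subset (the conditional expectation of g
given the non-missing tests), then standardized. The Bartlett alternative is
not exposed because downstream models standardize the scores anyway, making
the two methods differ only by the determinacy factor. The population
correlation between ĝ and true g is the factor determinacy
√(λᵀΣ⁻¹λ); the recovery tests use this closed form as their oracle.

An important consequence: **regressing estimated factor scores on an
exposure attenuates the standardized coefficient by the determinacy factor**
(≈0.82 under the default synthetic battery). Effect-recovery and
CI-coverage tests therefore regress the generator's latent g; the factor
scoring machinery is validated separately against the determinacy oracle.
Users analysing real data should expect the same attenuation — it is
intrinsic to factor-score regression, not a defect.

gFA/gMD are first principal components of the standardized tract
correlation matrix; the variance share is λ₁/p, the component sign is fixed
so the mean loading is positive, and a single-tract table degenerates to the
standardized tract itself.

## Association battery

Per model: outliers are removed (4 SD from the mean when |skewness| ≤ 1,
else 4 IQR from the median; zeroes of zero-inflated variables — burden and
prescription counts — are set aside before computing bounds and never
flagged), the sample is restricted to complete cases, numeric variables are
standardized on that sample, categorical covariates enter as indicator
contrasts against their most frequent level, and OLS is fit. The base
covariate template contains age, exposure-window length, data supplier,
deprivation, smoking, alcohol frequency, physical activity, BMI, APOE
carrier class, comorbidity count and seven disease-history flags; the scale
model optionally adds the per-scale non-anticholinergic count ("after
adjustment for polypharmacy"). Imaging models additionally include sex,
age², age×sex, age²×sex, scanner head-position coordinates, ethnicity and
assessment centre (the age²×sex term is our reading of an ambiguous
published covariate listing, switchable in code). Volumes are corrected for
head size by multiplying with the T1-based scaling factor before
standardization.

p-values are standard-normal (2(1−Φ(|β/SE|))) rather than t-based so that
the FDR-consistent interval is exact: within a family of m models, BH
rejects k*, the critical level is p_crit = k*·α/m (α/m when nothing is
rejected), and every CI has half-width z(1−p_crit/2)·SE — a CI excludes zero
precisely when the model is FDR-significant. Each results family
(scales×g, scales×brain, classes×g, classes×brain, per-test, per-region,
per-tract, gFA/gMD) is adjusted separately.

The battery selects the scale with the largest |β| against g for the
class-level, per-test and imaging families, mirroring the strongest-scale
convention. The scale-size correlation (Pearson r between a scale's drug
count and its |β|) is computed on both the polypharmacy-adjusted and
unadjusted families; the unadjusted variant is the cleaner read-out of
coverage-proportional effects because the per-scale polypharmacy covariate
is strongly collinear with burden. Sensitivity analyses invert the stage-10
exclusion (burden from only the 365 days before assessment) and add an
AChB×age product term formed from standardized components.

## Synthetic data: what it emulates and what it does not

The generators plant known truth so every downstream stage can be checked
quantitatively:

* **Catalogue/scales.** Stylized generics with brand aliases, WHO-style ATC
  codes spanning the anatomical groups, route profiles, and combination
  products. Scales draw nested drug sets from one consensus ranking —
  published scales likewise share a core of undisputed anticholinergics and
  diverge in their marginal entries — so scale coverage ties monotonically
  to how much of the true exposure a scale measures. Potency assignments
  still differ between scales, and the largest scale carries
  improbable-action flags.
* **Prescriptions.** Per participant-year counts are Poisson with rates
  increasing in age and comorbidity (the confounding structure); streams
  contain brands, combinations, non-systemic routes and an exactly counted
  set of planted violations (empty names, unmatched names, missing and
  impossible dates, post-death issues), each constructed to be removed at
  exactly one cascade stage.
* **Cognition.** g is a unit-variance linear combination of standardized
  burden (planted β, default −0.2), the observed confounders, a direct
  polypharmacy effect and noise; test scores are λ·g plus residuals with the
  configured residual correlations; one test is binarized by thresholding;
  four tests are missing outside the imaging subsample.
* **Imaging.** Volumes decline with age and share a global-size factor, with
  a head-size scaling column; FA/MD tracts follow equicorrelation models
  targeting first-PC variance shares of 0.44 and 0.50; the planted burden
  effect defaults to zero everywhere.
* **Direct exposure draws.** Monte-Carlo studies use
  `simulate_exposure`, which draws burden as a confounded zero-inflated
  variable directly: a logistic gate carries the confounding and the
  positive part is right-skewed but *bounded*. The bound is deliberate:
  with an unbounded heavy tail the 4-SD/4-IQR outlier rule truncates the
  exposure and shrinks the standardized coefficient, leaving no well-defined
  "true" standardized effect to recover. The non-anticholinergic count is
  correlated with burden given the covariates, so adjusting for it
  attenuates the burden coefficient by ≈30% under the defaults (the direct
  polypharmacy effect −0.22 was calibrated once to that design point).

What passing tests establish: the cascade removes exactly what it should;
scoring agrees with brute-force enumeration; CFA and OLS estimators recover
planted parameters at their nominal precision; FDR and its CIs are
calibrated under the null and cover under the alternative. What they do not
establish: realism of covariate distributions, dispensing/adherence
behaviour (issued is treated as exposed), dose effects, longitudinal
within-person cognitive change, or anything about effect sizes in real
cohorts.

## Problem sizes and reproducibility

Default study sizes were chosen so the full check suite runs on a single
CPU: parameter-recovery fits at n = 20 000; CI coverage over 50 replicates;
null FDR calibration over 200 replicate families of 100 outcomes at
n = 800; scale-size correlation over 100 replicates at n = 2 500 with a
reduced prescribing rate. One master seed fans out to per-generator child
seeds (`spawn_seeds`), every generator is deterministic given its seed, and
`run_all` writes a provenance manifest (config hash, seed, package versions,
per-stage row counts) sufficient to reproduce a run bit-for-bit.

## Known limitations

* The CFA treats the binary indicator as continuous; with very low
  prevalence this biases its loading toward zero.
* Under pure-noise data the size of any single loading is not identified
  (only the induced shared variance is ~0) — a known indeterminacy of ML
  factor analysis, surfaced in the tests.
* Stage 6 (supplier coverage end) defaults to the window end; real extracts
  need the supplier-specific last complete year supplied in config.
* Complete-case analysis per model; no imputation.
* The first-year removal (stage 7) is applied per participant, not per
  supplier, when a participant's records span suppliers.
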