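# Methods

This note documents the statistical models implemented in `isoniche`, the
assumptions they rest on, the defaults and why they were chosen, and what
the synthetic-data generator does and does not emulate.

## Isotope pre-processing

Isotope ratios are expressed in δ-notation,
δ(‰) = (R_sample/R_standard − 1)·10³, against VPDB
(R = 0.0112372) for carbon and atmospheric N₂ (R = 0.0036765) for
nitrogen.

**Lipid normalisation.** Lipids are depleted in ¹³C relative to protein,
so bulk δ¹³C of lipid-rich tissue is biased low. We apply the
aquatic-animal arithmetic normalisation
δ¹³C′ = δ¹³C − 3.32 + 0.99·(C:N)
whenever the mass C:N ratio exceeds 3.6, the conventional threshold
below which tissue is considered lipid-poor. The constants are
configurable; values at or below the threshold pass through unchanged and
are logged. The correction is monotone increasing in C:N, so it never
reorders individuals within a fixed δ¹³C.

**Anomalies and ED.** Because treatments may sit on different isotopic
baselines (different sediments or food sources), all cross-treatment
modelling uses anomalies: the individual value minus its treatment mean,
per axis. Each individual's Euclidean distance to its group centroid,
ED = √(δ¹³Cₐ² + δ¹⁵Nₐ²), is the per-individual counterpart of the CD
niche metric (mean ED over a group equals CD exactly). Anomalies default
to treatment-level grouping; initial (pre-experiment) groups are
normalised against their own centroid, since no treatment centroid
meaningfully applies to them.

## Niche metrics

For one group of (δ¹³C, δ¹⁵N) points:

* **NR, CR** — axis ranges (max − min) of δ¹⁵N and δ¹³C.
* **TA** — area of the 2-D convex hull (exact, via Qhull). Needs at
  least 3 non-collinear points; degenerate clouds report TA = 0 with a
  flag rather than an error, since collinear bootstrap resamples are
  legitimate.
* **CD** — mean Euclidean distance to the centroid.
* **MNND, SDNND** — mean and sample sd (ddof = 1) of each point's
  distance to its nearest other point. Duplicate points contribute
  distance 0 and are kept as-is.
* **SEA, SEAc** — the standard ellipse has semi-axes equal to the square
  roots of the sample-covariance eigenvalues (no χ² scaling), hence
  SEA = π·√(λ₁λ₂) = π·√det(S) with S computed with denominator n − 1.
  SEAc = SEA·(n−1)/(n−2) corrects the small-sample bias; SEAc ≥ SEA
  always.

Areas are in ‰², distances in ‰. TA, CD, MNND, SDNND and SEA are
invariant to translation and rotation of the isotope plane; NR and CR
are axis-aligned by definition and only translation-invariant.

**Bootstrap comparison of unequal groups.** Group sizes in mesocosm
experiments differ several-fold, and hull-based metrics grow with n. For
comparability every group is therefore resampled with replacement at the
*minimum* group size (2000 replicates by default), and each metric is
summarised by its resample mean with equal-tailed 50/75/95% percentile
intervals, which are nested by construction. Resampling pools individuals
within a group, ignoring mesocosm membership: the comparison is between
treatment groups, not between mesocosms.

**Bayesian ellipse areas (SEA_B).** The population covariance Σ receives
a conjugate Normal–Inverse-Wishart prior with degrees of freedom
ν₀ = 3 (= dimension + 1, the smallest proper choice), scale matrix
10⁻³·I, and a mean prior centred on the sample mean with weak precision
κ₀ = 10⁻³. The posterior over Σ is then Inverse-Wishart with
ν_n = ν₀ + n and scale Λ₀ + centred scatter, sampled exactly — no MCMC
is needed. Each draw maps to an area SEA_B = π√det(Σ). With these vague
hyperparameters the posterior mean approaches SEAc as n grows (the
package's consistency tests verify agreement within 2% at n = 500).
Intervals are equal-tailed percentiles by default; a highest-density
option exists but is not the default since the two differ negligibly for
these unimodal posteriors.

Two groups are compared by the exceedance probability
P(SEA_B,a > SEA_B,b), computed over paired posterior draws (cycled if the
draw counts differ, ties split evenly). The significance call at level
0.95 is two-sided: the groups are "different" when the exceedance
probability leaves the central 95% band, i.e. falls outside
[0.025, 0.975]. This convention makes the null behaviour match a
two-sided 5% test (≈5% of same-distribution pairs flagged), which the
calibration tests confirm; a one-sided 0.95 cut would double that rate.

## Hypothesis-testing stages

**Variance heterogeneity (H1).** Levene's test — a one-way ANOVA on
absolute deviations from each group's centre — compares the variances of
physiological and isotope endpoints between treatments. Centering
defaults to the group mean (Levene's original form); median centering
(Brown–Forsythe) is a config option. Groups whose members are all
identical yield a degenerate statistic of 0 with p = 1 rather than NaN.

**Mixed models.** Treatment effects on ED and on physiology are
estimated with a random intercept per (treatment, mesocosm) pair,
encoding mesocosm nested under treatment; the random effect is always
retained because the mesocosms are part of the design. Gaussian responses
are fitted by REML (t statistics on fixed effects). Poisson counts
(fecundity) are fitted by maximum likelihood with a log link, integrating
the random intercept out with 25-node Gauss–Hermite quadrature and taking
standard errors from the numerical observed information (z statistics);
this component is implemented in the package because the REML machinery
used for Gaussian responses does not extend to count data. An estimated
random-intercept variance on the zero boundary is returned as a valid fit
with a `boundary` flag; boundary fits are cross-checked internally
against the OLS solution, to which GLS collapses when the cluster
variance is zero. Optimizer non-convergence (after a ladder of
fallbacks) raises an explicit error with diagnostics.

AIC is computed as 2k − 2·logL with k counting all estimated parameters
(fixed effects plus variance components). For REML fits the restricted
likelihood is used, so AIC comparisons are only meaningful between models
sharing the same fixed-effect structure.

**Anomaly models (H2).** Linear models relate δ¹⁵Nₐ and δ¹³Cₐ to
physiology (body mass, parasite presence, fecundity, embryo viability,
mortality in the exposure experiment; body mass, RNA:DNA, C:N, oxygen
penetration depth, mortality in the feeding experiment). The identity
link uses OLS with t statistics; a Gaussian GLM with log link is
available for strictly positive responses such as absolute isotope
changes. Every non-empty predictor subset is fitted on the identical
complete-case record set (so AICs are comparable), and the minimum-AIC
model is reported, with ties broken toward fewer parameters. Note that
minimum-AIC selection admits an irrelevant predictor with asymptotic
probability P(χ²₁ > 2) ≈ 0.16; "most parsimonious" therefore means
lowest-AIC, not oracle-true, and the selection-consistency tests assert
exactly that behaviour.

**Stress discriminator (H3).** A logistic regression of stressed(1) vs
reference(0) individuals on isotope anomalies, ED and growth/reproductive
endpoints, with the predictor set chosen by AIC (the intercept-only model
is a candidate, so a no-signal dataset usually yields a chance-level
discriminator rather than an overfitted one). Odds ratios are
exp(coefficient). Performance is summarised by the ROC curve of the
fitted probabilities: AUC (equal to the normalised Mann–Whitney U
statistic between classes) and sensitivity/specificity at the cutoff
maximising Youden's J. Complete or quasi-complete separation raises a
warning and flags the report; the coefficients are then unstable and only
the ranking (hence AUC) is trustworthy. Predictors enter raw by default.
A within-treatment z-scoring option for C:N exists, but it is not the
default for the discriminator because z-scoring within the very groups
being predicted removes the between-treatment signal and leaks the group
label into the features. In-sample ROC on a fitted model is optimistic;
with the AIC gate the null-condition mean AUC stays near 0.5 (verified
by simulation), but out-of-sample validation is still the user's
responsibility for real data.

Multiple-testing correction is not applied across endpoint tests by
default (a Holm option exists), matching the exploratory reporting style
of mesocosm screening studies.

## The synthetic-data generator

The generator emulates two replicated mesocosm experiments on a
deposit-feeding amphipod:

* **Experiment 1** — contaminated vs reference sediment, 7 mesocosms × 25
  individuals per treatment plus an initial group (3 × 5), with
  reproductive endpoints: Poisson fecundity (means 29 / 23 embryos),
  beta-binomial embryo viability (mean proportions 0.920 / 0.715 with sd
  0.16 / 0.36 on the proportion scale), parasite prevalence 0.27 / 0.25,
  survival 63 ± 11% / 74 ± 13%.
* **Experiment 2** — four feeding regimes (reference sediment, lignin,
  diatoms, Tetraphyll), 5 mesocosms × 24 individuals plus initials, with
  body mass, RNA:DNA and C:N endpoints and a mesocosm-level oxygen
  penetration depth (12.3 ± 2.1 mm). The low-quality regimes (reference,
  lignin) are the stressed class.

Per treatment, isotope values are bivariate normal around the treatment
mean with the treatment's total covariance; a fraction (default 20%) of
each axis's variance is moved onto a mesocosm random intercept, so the
declared sds remain *total* sds. The 20% split is a declared assumption —
the within- vs between-mesocosm decomposition is not identifiable from
group-level summaries. Survival acts as binomial thinning of the stocked
individuals per mesocosm. Stress inflates the *total* isotope covariance
by a single factor κ (both the mesocosm and individual components), so
that the expected stressed:reference SEA ratio equals κ exactly; per-axis
inflation is configurable. Covariate→isotope links (e.g. body mass →
δ¹⁵N, mortality → δ¹³C) are applied additively to within-treatment
*centred* covariates, preserving the treatment means while adding the
correlation structure the anomaly models look for; default coefficients
follow the sign pattern of the corresponding regression estimates
(positive parasite and body-mass effects on δ¹⁵N in the exposure
experiment, negative body-mass effect in the feeding experiment). The
generator draws δ¹³C on the lipid-corrected scale and back-computes raw
values from each individual's C:N, so the pre-processing stage recovers
the intended cloud exactly.

What the generator does **not** emulate: gravidity (every experiment-1
individual carries reproductive endpoints, whereas real datasets score
only gravid females, giving differing n per analysis); temporal isotope
turnover during the incubation; non-normal isotope clouds; measurement
error beyond the declared sds; and any mechanistic fractionation model.
Passing calibration tests therefore demonstrates correctness of the
estimators under the assumed data-generating process, not robustness to
real-data pathologies such as outliers (handled separately via declared
outlier replacement) or skewed signatures.

## Numerical and design choices

* Outliers are user-declared by specimen id and replaced with the mean
  of the non-flagged members of their treatment, variable by variable;
  the operation is idempotent and logged. No automatic detection rule is
  offered.
* Missing optional physiology is represented as absent (never zero);
  every model stage drops incomplete records for its own variable set and
  logs the count.
* Seeds: one global seed spawns fixed per-stage substreams
  (`SeedSequence((seed, stage_id))`), so stages can be rerun
  independently with unchanged results. All exports embed the seed and
  package version, and a fixed config + seed reproduces every export
  byte for byte (the run log carries no timestamps).
* Logistic convergence: Newton iterations, tolerance 1e-8 on the
  log-likelihood, 100 iterations; BFGS fallback under separation.
* Degenerate inputs: singular covariance → SEA 0 with a flag; constant
  groups → explicit zero-spread errors in z-scoring; empty groups →
  errors naming the group.

## Problem sizes in the test suite

The simulation-based checks use: 100 replicate experiments for the
κ ∈ {2, 4} SEAc-ratio recovery and for each arm of the discriminator
calibration; 200 replicates for the mixed-model fixed-effect recovery
and the Bayesian null calibration (n = 50 per group); 2000 null
replicates for Levene's type-I error (n = 15 per group); 500 for the
null-AUC calibration; and 20 replicate n = 500 datasets for Bayesian
consistency. These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands while keeping the default test run fast.

## Known limitations

* The Bayesian SEA_B sampler is exact-conjugate, not an MCMC replication
  of any particular existing sampler; hyperparameters differ at the
  third decimal from other "vague" choices, so third-party SEA_B values
  will agree only approximately (consistency with SEAc is the contract).
* Only Gaussian and Poisson mixed families are supported; no overlap
  metrics between ellipses, no mixing models, no trophic-position
  estimation.
* The ED mixed model treats mesocosm-level covariates (survival, oxygen)
  as fixed regressors; measurement error in them is ignored.
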