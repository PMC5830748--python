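# isoniche

Isotopic-niche metrics and physiological-stress diagnostics for bivariate
stable-isotope data.

## The problem

The *isotopic niche* — the region a population occupies in bivariate
δ¹³C–δ¹⁵N space — is widely used as a proxy for trophic niche breadth.
The approach assumes that diet–consumer isotope fractionation varies
negligibly among individuals. Under physiological stress (poor nutrition,
contaminant exposure, parasite infestation, low oxygen) that assumption
breaks: inter-individual variability in metabolism inflates the variance
of the isotope signature and the apparent niche *expands* without any
dietary divergence. `isoniche` implements the full analysis chain needed
to quantify this effect and to turn it around into a diagnostic: can
isotope variability, combined with growth and condition endpoints,
identify a stressed population?

The package is aimed at trophic ecologists and ecotoxicologists working
with individual-level consumer records from replicated (mesocosm)
designs.

## What it computes

Pre-processing (`isoniche.prep`)

* δ-notation: δ(‰) = (R_sample/R_standard − 1) × 10³ (VPDB for C,
  atmospheric N₂ for N);
* lipid normalisation of δ¹³C from the mass C:N ratio,
  δ¹³C′ = δ¹³C − 3.32 + 0.99·C:N, applied above the C:N threshold 3.6;
* within-group anomalies δ¹³Cₐ, δ¹⁵Nₐ (individual minus treatment mean)
  and the Euclidean distance to the group centroid
  ED = √(δ¹³Cₐ² + δ¹⁵Nₐ²).

Niche metrics (`isoniche.niche`)

* the six Layman metrics: NR, CR (axis ranges), TA (convex hull area),
  CD (mean distance to centroid), MNND and SDNND (mean/sd of
  nearest-neighbour distances);
* the standard ellipse area SEA = π√det(S) with S the sample covariance,
  and its small-sample correction SEAc = SEA·(n−1)/(n−2);
* bootstrap comparison of unequal groups (resampling every group at the
  minimum group size, 2000 replicates, nested 50/75/95% intervals);
* Bayesian posterior ellipse areas SEA_B from a conjugate
  Normal–Inverse-Wishart model, with pairwise exceedance probabilities
  P(SEA_B,a > SEA_B,b) and a two-sided significance call at 0.95.

Inference (`isoniche.inference`)

* Levene's test for variance heterogeneity between treatments;
* random-intercept mixed models (mesocosm nested under treatment):
  Gaussian by REML, Poisson counts by maximum likelihood with
  Gauss–Hermite quadrature;
* linear models of isotope anomalies on physiology with AIC selection of
  the most parsimonious predictor set;
* a logistic stress discriminator reported with odds ratios, ROC curve,
  AUC, and sensitivity/specificity at the Youden-J cutoff.

Synthetic experiments (`isoniche.simulate`) generate record sets with the
assumed structure — treatment-specific bivariate-normal isotope clouds
with stress covariance inflation κ, mesocosm random intercepts, binomial
survival thinning, beta-binomial embryo viability, covariate→isotope
links — parameterised after a contaminated-sediment exposure
(experiment 1) and a four-level feeding-regime experiment (experiment 2)
on a deposit-feeding amphipod.

## Worked example

```python
from isoniche import RunConfig, run_pipeline

cfg = RunConfig(experiment=1, simulate=True, seed=7, out_dir="out_exp1")
res = run_pipeline(cfg)
print(res.group_metrics[["group", "n", "NR", "CR", "TA", "CD", "SEAc"]]
      .round(3).to_string(index=False))
```

```
    group   n    NR    CR    TA    CD  SEAc
  initial  15 1.022 1.089 0.699 0.390 0.317
reference 120 1.678 2.400 2.296 0.451 0.388
 exposure 131 1.983 2.670 3.696 0.639 0.751
```

The contaminant-exposed group's standard ellipse (SEAc 0.75 ‰²) is about
twice the reference group's (0.39 ‰²) even though both were generated on
the same diet — the apparent niche expansion produced by stress-inflated
variance. The downstream stages agree:

```
              estimate      se    stat       p
Intercept       0.1423  0.1165  1.2208  0.2221
stressed        0.1463  0.0413  3.5438  0.0004
survival_pct    0.0045  0.0017  2.6933  0.0071

P(SEA_B initial > reference) = 0.062  significant: False
P(SEA_B initial > exposure) = 0.000  significant: True
P(SEA_B reference > exposure) = 0.000  significant: True

discriminator: ['ed', 'fecundity', 've_pct']  AUC = 0.900
sensitivity = 0.86  specificity = 0.81
```

The mixed model finds a positive stress effect on the distance to
centroid (ED), the Bayesian comparison flags the exposed ellipse as
larger than the reference, and the AIC-selected logistic discriminator
separates stressed from reference individuals with AUC 0.90.

The same run is available from the shell:

```sh
isoniche all --experiment 1 --seed 7 --out-dir out_exp1
```

or stage by stage (`simulate`, `prep`, `metrics`, `compare`, `models`,
`classify`), each reading the previous stage's exports. All outputs are
plain CSV/JSON, embed the seed and package version, and are byte-for-byte
reproducible under a fixed seed.

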