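# igglycome

Analysis pipeline for human IgG N-glycome population studies: it turns raw
glycan measurements — centroid LC-MS peak lists of subclass-specific IgG Fc
glycopeptides, and 24-peak HILIC-UPLC area tables of the total IgG
glycome — into relative glycoform abundances, derived glycosylation traits,
and population-level statistics: how much trait variability is explained by
a subject's age, sex and country of residence, and how country-level trait
averages relate to development indicators.

It is written for glycomics / glycoproteomics groups running multi-cohort
IgG studies, and ships a synthetic-data generator that reproduces the
statistical structure of such a study (country random effects, age and sex
fixed effects, plate batch effects, compositional noise, mass-calibration
drift), so the whole pipeline is testable without access to cohort data.

## What it computes

**Quantification (LC-MS).** Each sample × subclass centroid spectrum is
internally calibrated with an affine model m/z′ = a·m/z + b fitted on a
defined list of high-signal glycopeptide calibrants (accepted on
signal-to-noise and isotope-pattern cosine criteria). Signals of a
20-glycoform panel per subclass (IgG1/IgG2/IgG4; IgG3 co-elutes and is not
separable) are extracted in narrow m/z windows; the first four
isotopologues of the 2+ and 3+ ions are summed per species

&nbsp;&nbsp;&nbsp;&nbsp;A(species) = Σ_{z∈{2,3}} Σ_{k=0..3} I(m/z_{z,k}),

and species are total-area normalized within each subclass to percentages.
Theoretical m/z grids come from elemental compositions and isotope
envelopes computed by polynomial convolution of per-element isotope
distributions. The UPLC path total-area normalizes raw 24-peak tables.

**Derived traits.** For a trait T with indicator set S (glycoforms sharing
a structural feature), T = Σ_{i∈S} p_i with p the normalized abundances:
agalactosylation (0 galactoses), mono- and digalactosylation (1, 2),
sialylation (≥1 NeuAc), bisecting GlcNAc, and — total glycome only — core
fucosylation. By construction agal + mono + digal = 100 per sample.

**Batch correction.** Log-transformed tables are adjusted with a
parametric empirical-Bayes location/scale correction (normal prior on
batch locations, inverse-gamma on scales, iterative joint solution),
protecting country, age and sex; it matches Bioconductor's `sva::ComBat`
to ~1e-6 on shared inputs.

**Variance decomposition.** Per trait, a random-intercept mixed model

&nbsp;&nbsp;&nbsp;&nbsp;y_ij = β₀ + β_age·age_ij + β_sex·sex_ij + u_j + ε_ij,
u_j ~ N(0, σ²_country), ε_ij ~ N(0, σ²_e)

is fitted by REML (one-dimensional profile over λ = σ²_country/σ²_e with
closed-form GLS, boundary λ=0 admissible). Variance explained follows the
marginal/conditional R² framework for mixed models: each component is a
percentage of var(Xβ̂) + σ̂²_country + σ̂²_e. The country effect is tested
with a likelihood-ratio test against χ²₁ (50:50 boundary mixture
optional).

**Ecological correlation.** Traits are averaged per country and tested
against country-level development indicators with Pearson's r, two-sided
p from t = r·√((n−2)/(1−r²)), and Bonferroni adjustment by the number of
tests performed.

## Worked example

```python
import warnings
import pandas as pd
import igglycome as ig

# 1. simulate a cohort (6 countries x 60 subjects)
design = ig.CohortDesign(
    countries=[ig.CountrySpec(name, 60) for name in
               ("China", "Croatia", "Germany", "Sweden", "Thailand", "Uganda")],
    seed=0)
cohort = ig.simulate_cohort(design)

# 2. render LC-MS peak lists with a +30 ppm miscalibration and quantify
spectra = ig.render_spectra(cohort, drift_ppm=30.0, mz_jitter_ppm=1.0,
                            samples=cohort.samples[:3])
abundance, qc = ig.quantify_fc_spectra(spectra.values())
print(qc[["sample", "subclass", "n_calibrants", "median_abs_residual_ppm"]].head(3))
print(abundance["IgG1"][["G0F", "G1F", "G2F", "G2FS1"]].round(2))

# 3. derive traits on the full cohort and decompose their variance
traits = ig.derive_fc_traits(pd.concat(cohort.compositions, axis=1))
model = ig.TraitVarianceModel.from_dataframe(
    traits["IgG1"].join(cohort.metadata), "monogalactosylation")
print(model.fit().summary())
```

prints

```
   sample subclass  n_calibrants  median_abs_residual_ppm
0  S00001     IgG1            12                 0.518326
1  S00001     IgG2            12                 0.969880
2  S00001     IgG4            12                 0.286260

glycoform    G0F    G1F    G2F  G2FS1
sample
S00001     23.52  22.79  16.19   8.88
S00002     12.23  20.58  25.22  15.31
S00003     15.50  21.12  20.58  14.91

Random-intercept mixed model (REML): monogalactosylation
================================================================
n obs                                360
n countries                            6

                      coef     std err
intercept         28.55406     0.53510
age                0.05780     0.00735
sex[M]             0.04798     0.23232

sigma2 country                   0.89056
sigma2 residual                  4.78643
ICC (country)                     0.1569

Variance explained (% of total):
  country                          13.69
  age                              12.73
  sex                               0.01
  residual                         73.59
LRT country p-value            9.969e-10
```

The calibration report shows the injected 30 ppm drift removed to
sub-ppm residuals on 12 calibrant ions; the abundance table is the
normalized IgG1 panel (four of 20 columns shown); the model summary
reports the fitted fixed effects, the variance components, and the
percentage of monogalactosylation variability attributed to country of
residence, age and sex, with the likelihood-ratio p-value of the country
random intercept.

A command-line surface mirrors the stages
(`igg-glyco simulate | quantify-fc | quantify-uplc | traits | preprocess |
varcomp | correlate | run-all`); `run-all` is driven by a single YAML
config, e.g.

```yaml
out_dir: results/demo
seed: 0
n_countries: 4
n_per_country: 24
drift_ppm: 30.0
```

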