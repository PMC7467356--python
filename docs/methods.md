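# Methods

This note documents the models and procedures implemented in `igglycome`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that affect
results.

## Chemistry layer

Glycopeptide masses are assembled from residue-summed amino-acid
compositions plus one water, plus dehydrated monosaccharide residues
(Hex C₆H₁₀O₅, HexNAc C₈H₁₃NO₅, dHex C₆H₁₀O₄, NeuAc C₁₁H₁₇NO₈).
Monoisotopic masses use lightest-isotope masses; ions are computed as
(M + k·1.0033548 + z·1.0072765)/z for charge z ∈ {2, 3} and isotopologue
offset k ∈ {0..3}. Isotope envelopes are aggregated by nucleon-number
offset (isobaric fine structure ignored — adequate below ~60k resolving
power) and computed by polynomial convolution of per-element isotopic
distributions with binary exponentiation; the full distribution sums to
1 exactly, so truncation loss is measurable. Across the default panel
the first four isotopologues retain 85–93% of the signal (heavier,
disialylated species retain least).

Default backbones are the tryptic Fc peptides EEQYNSTYR (IgG1),
EEQFNSTFR (IgG2) and EEQFNSTYR (IgG4). The IgG3 glycopeptide is
allotype-dependent and co-elutes with IgG2 or IgG4, so it is not
modelled separately. The 20-glycoform panel (G0…G2FNS1, with core
fucose, bisecting GlcNAc and up to two NeuAc) ships as an editable YAML
schema; it is the conventional IgG Fc repertoire and reproduces the
standard species count, but any panel file with the same columns can be
substituted. All 480 panel ion positions (20 glycoforms × 3 subclasses ×
2 charges × 4 isotopologues) fall inside the 600–1800 m/z acquisition
window, and the smallest m/z gap between windows of different species is
4.33 Th, so the default 10 ppm extraction windows are collision-free
(the extractor still computes and warns on window overlaps for custom
panels or wide tolerances).

## Quantification

Internal calibration fits m/z′ = a·m/z + b by least squares on accepted
(observed, theoretical) monoisotopic pairs of a calibrant list (default:
the six most abundant species of the panel, both charge states, so 12
candidate ions). A candidate is accepted when (i) its signal-to-noise
ratio is ≥ 9 against a local noise floor and (ii) the cosine between its
observed and theoretical first-four isotopologue intensities is ≥ 0.95;
at least 5 accepted candidates are required, otherwise the sample is
flagged as a calibration failure (never silently passed through). The
noise floor is the median intensity within ±2 m/z after excluding all
known panel ion positions (shifted by the candidate's apparent drift):
excluding only the candidate's own envelope would let neighbouring
glycopeptide signals inflate the floor and reject valid calibrants. If
the window holds nothing but analyte signal the global non-analyte
median is used; a noise-free spectrum therefore has floor 0 and
unbounded S/N. Thresholds are package defaults, configurable; the
acquisition literature gives no canonical values.

Extraction windows are half-open, [c−tol, c+tol), making boundary
behaviour deterministic; the default tolerance is 10 ppm. Species
abundance is the sum over 8 cells (2 charges × 4 isotopologues), then
total-area normalized per subclass. Missing signals contribute 0 to the
subclass total; a fully absent subclass is marked missing rather than
0/0. The UPLC path checks the 24-column schema and total-area
normalizes.

## Synthetic-data generator

The generator defines the conditions under which the pipeline is
validated. Its default design mirrors the shape of a large multi-country
Fc study: 14 countries × 184 subjects (n = 2,576), ages 18–70, sexes
balanced, samples dealt round-robin onto 96-well plates after sorting by
(country, sex, age) so plates are balanced blocks.

A latent galactosylation score per subject,

g = β₀ + β_age·(age − 44) + β_sex·𝟙[female] + u_country + b_plate + ε,

with independent zero-mean Gaussian u, b, ε, is mapped to the
(agal, mono, digal) simplex by softmax(c·(−g, 0, g)) — monotone and
invertible in g — and each class share is distributed over that class's
glycoforms with fixed baseline proportions (the composition of adult
plasma IgG Fc, fucosylated neutral species dominant). Smaller analogous
latent scores tilt sialylated and bisected species multiplicatively
*within* each galactosylation class, so the galactosylation trio remains
exactly the softmax allocation. Defaults (β_age = −0.013/yr, sex offset
0.02, σ_country = 0.25, σ_plate = 0.05, σ_ε = 0.30, shape c = 1) put
country at ~30% and age at ~20% of latent variance — the regime reported
for galactosylation traits in multi-country IgG studies. Subclasses get
a fixed offset on g (+0.10 IgG1, −0.10 IgG2) plus small subclass noise.

Spectra are rendered per sample × subclass: peaks at the first four
isotopologues of both charge states of every non-zero glycoform,
intensity = abundance × isotopologue fraction × charge split (0.7/0.3),
with all m/z multiplied by (1 + drift·10⁻⁶) to inject a systematic
calibration error, optional per-peak ppm jitter, and uniform random
noise peaks (default mean intensity 2×10⁻⁴ of the per-spectrum scale:
the most abundant glycoform then has S/N ≈ 300, and minor species sit
near the detection limit — the realistic regime for a modern QTOF, and
consistent with weak non-fucosylated species being the first casualties
of data quality). By default isotopologue fractions are renormalized
over the four rendered peaks, so the emitted peaks carry the species'
entire signal and the pipeline's summation is exactly consistent with
the rendering; with `full_envelope=True` the first eight isotopologues
are rendered with absolute fractions, which exposes the
species-dependent ~7–15% truncation loss as a composition distortion of
up to a few tenths of a percentage point — useful for studying the
truncation bias, but then the generator and the 4-peak summation rule
are deliberately mismatched.

The UPLC table maps the same latents onto 24 annotated peaks (same
within-class tilt construction, plus a core-fucose latent) and
multiplies by an arbitrary per-sample total area and optional
multiplicative noise. Indicators are affine functions of the countries'
realized mean latent score plus Gaussian noise scaled so the expected
country-level Pearson correlation equals a target r.

What the generator does **not** emulate: chromatographic peak shapes and
co-elution, missing values, between-run retention drift, Fab-glycan
contribution differences, non-Gaussian country effects, and real
indicator co-dependency structure. Tests passing on synthetic data
therefore validate the computational pipeline — calibration, extraction,
normalization, trait algebra, batch correction, model fitting — not the
biology of any particular cohort.

## Mixed-model benchmark and scoring rule

For validating the variance decomposition, traits are simulated directly
from the linear mixed-model data law (y = β₀ + β_age·age + β_sex·sex +
u_country + ε) with prescribed variance shares — by default country 38%,
age 2.6%, sex 0.1% of total, the regime of the strongest reported
country association (monogalactosylation). The glycoform-level
generator's softmax map makes trait-scale shares non-analytic, so the
LMM benchmark is the correct object for scoring the estimator.

Recovery is scored against the *realized* shares of each draw: the
between-country variance of the 14 drawn intercepts (ddof = 1), the
realized variance of the fixed predictor, and the realized residual
variance. With only 14 countries the realized between-country spread
fluctuates ±~40% around its design value; conditional on a draw the
REML estimator targets the realized spread (in the balanced case its
conditional expectation is exactly the ddof-1 between-group variance),
so comparing against the design constant would measure draw noise and a
Jensen bias of the share ratio, not estimator quality. Measured mean
bias of the country share over 200 seeds is below 0.1 percentage points.

## Numerical choices

- **REML profile.** For fixed λ the marginal covariance is block
  compound-symmetric, so GLS reduces to per-group sufficient statistics
  (O(groups·p²) per λ). λ ≥ 0 is optimized on a log grid (81 points,
  10⁻⁶–10⁴) followed by bounded Brent refinement and a narrow polishing
  pass; the boundary λ = 0 is compared explicitly and is admissible. At
  λ = 0 the fit equals OLS to 1e-10; in balanced designs the variance
  components match closed-form ANOVA estimators to ~1e-7 relative.
- **LRT.** Both models are refitted by ML on the same data; the statistic
  is referred to χ²₁ by default (conservative under the boundary null),
  with the 50:50 χ²₀:χ²₁ mixture available (`boundary_mixture=True`),
  which exactly halves the p-value for positive statistics.
- **Variance shares.** Per-variable fixed shares use variances of the
  centered components; their covariance remainder is reported separately
  (`fixed_covariance`). Age and sex are near-orthogonal under the
  blocked design, so the remainder is ~0; the decomposition is invariant
  to affine sex recoding and age centering up to the profile tolerance.
- **Batch correction.** The parametric empirical-Bayes variant, matching
  the reference R implementation to ~1e-6 (verified against
  `sva::ComBat` in the test suite); convergence 1e-6, max 200
  iterations. Country, age and sex are protected by default so the
  correction cannot absorb the effects under study. Singleton batches
  fall back to location-only correction with a warning. Two properties
  sometimes assumed of batch correction do **not** hold for any
  data-driven method and are documented rather than asserted: the
  correction is a contraction, not a projection (a second pass still
  changes values at the δ/√n scale), and post-correction between-batch
  F-test p-values are stochastically conservative, not uniform — the EB
  estimate removes the *realized* batch means (fully when shifts are
  real, about half under the null), deflating the F statistics.
- **Log transform.** Natural log; zeros are replaced by half the
  smallest positive value of their column first; negatives are rejected.
- **Correlation.** Pairwise-complete observations, minimum 3 countries;
  zero-variance vectors yield an explicit `undefined` status. The
  Bonferroni multiplier defaults to the number of tests actually
  performed in the call, never a hard-coded constant.
- **Determinism.** Every stochastic operation takes or derives a seed;
  the same design/config yields byte-identical tables and CSVs.

## Problem sizes used in validation

The test suite and the acceptance script use reduced but structurally
faithful sizes chosen as the package's own validation design: 2-country
cohorts (n = 40) for spectra round trips, the full 14 × 184 design for
plate-assignment, correlation and batch diagnostics, 200 independent
draws for the variance-share benchmark, 500 replicates for the
correlation-recovery band, 10⁶ permutations for the Pearson oracle, and
300 null simulations for LRT calibration.

## Known limitations

- The 24-peak UPLC annotation reflects the conventional 2-AB IgG peak
  assignment; laboratory-specific peak characterizations should replace
  the shipped YAML (the trait formulas are data, not code).
- Sialylation is presence-weighted by default; count weighting is
  available (`sialylation="count"`) and can exceed 100 for disialylated
  species by construction.
- The calibration model is affine; higher-order mass-error shapes
  (common on TOF instruments over wide m/z ranges) are not modelled.
- One random intercept (country) only; nested or crossed random effects
  (e.g. cohort within country) are out of scope.
- Ecological correlations are descriptive; no causal interpretation,
  imputation of missing indicators, or indicator co-dependency
  modelling is attempted.
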