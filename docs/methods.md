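# Methods

## Model and assumptions

Two-sample MR treats each genetic instrument *j* as a natural experiment.
The identifying assumptions are the usual three: the instrument is
(a) associated with the exposure, (b) independent of confounders, and
(c) affects the outcome only through the exposure.  The package estimates
the causal effect θ (log odds of outcome per unit of exposure liability,
for binary traits) from harmonized per-variant pairs (β̂xⱼ, σxⱼ, β̂yⱼ, σyⱼ).

All estimators use the no-measurement-error (NOME) convention: ratio SEs
are σyⱼ/|β̂xⱼ|, ignoring σxⱼ.  This matches the standard IVW derivation,
keeps Cochran's Q on k−1 degrees of freedom, and is accurate when outcome
SEs dominate exposure SEs — the usual situation when the exposure comes
from a biobank-scale GWAS and the outcome from a disease GWAS with far
fewer cases.  Its residual footprint is quantified below.

Estimator conventions, chosen to be mutually consistent and conservative:

* IVW p-values from the normal distribution; the multiplicative
  random-effects SE inflation √(Q/(k−1)) is floored at 1 (no
  under-dispersion credit).
* MR-Egger is fit after orienting every pair to β̂xⱼ ≥ 0 (the intercept is
  only meaningful on the exposure-increasing orientation); coefficient SEs
  carry the multiplicative scale max(1, √(RSS_w/(k−2))) and p-values use
  the t distribution with k−2 df.
* The weighted median interpolates the ordered ratio estimates at
  cumulative weight midpoint 0.5; its SE is the SD of a seeded parametric
  bootstrap (default 1,000 replicates) redrawing both β̂x and β̂y from
  their sampling distributions.  A closed-form SE approximation exists but
  the bootstrap makes fewer assumptions; the replicate count is
  configurable.
* MR-PRESSO residuals are taken against leave-one-out IVW slopes so an
  outlier cannot mask itself; empirical p-values use (1+b)/(1+B) and are
  therefore never zero; per-variant p-values are Bonferroni-multiplied by
  k and capped at 1.  The outlier test is reported unconditionally (not
  gated on a significant global test); defaults are 1,000 simulations and
  outlier α = 0.05.  The distortion null removes 1,000 random subsets of
  the observed outlier count.
* All confidence intervals are θ̂ ± 1.96·SE.

## Pipeline decision rules

`run_mr` chains significance filter (p < 5×10⁻⁸) → LD clumping
(r² < 0.001 within 10,000 kb; greedy by ascending p, ties broken by
variant ID for determinism; distance-only when no LD matrix is supplied,
since none is bundled) → F > 10 → optional confounder exclusion
(p < 5×10⁻⁸ against a local association table — a file, not a web query,
to keep runs hermetic) → harmonization → estimators.  The primary estimate
is the multiplicative random-effects IVW when Q's p < 0.05, fixed-effects
IVW otherwise.  Every dropped variant is logged with a reason and the
report's attrition counts partition the input exactly.

Harmonization resolves swapped orientations by negating β̂y, attempts
strand-complement resolution before dropping a variant, and handles
palindromic (A/T, C/G) variants by effect-allele frequency: both EAFs must
lie outside 0.5 ± 0.08 and agree in side, otherwise the variant is dropped
and counted.  The band and an optional drop-all-palindromes policy are
configurable, since published workflows differ.  Harmonization never
alters SEs.

Mediation is the classic product-of-coefficients two-step form; the
mediator→outcome leg is deliberately univariable (not exposure-adjusted).
Proportions mediated outside [0, 1] are reported with a warning, not
truncated.  The delta-method SE of β2·β3 assumes independent legs (true in
a two-sample design).  Multiple-testing correction across outcomes is
deliberately not applied; reports carry raw p-values only.

## The synthetic-data generator

`simulate_pair` draws true instrument effects βxⱼ ~ N(0, 0.02) with |βxⱼ|
floored at 6σx (expected F ≥ 37), observes them with σ = 1/√n_eff, and
builds outcome means θβxⱼ + sign(βxⱼ)·αⱼ.  Direct effects αⱼ are defined
on the exposure-increasing allele, so directional pleiotropy survives the
arbitrary allele orientation of the emitted files.  Regimes: none,
balanced N(0, τ), directional N(μα, τ), and InSIDE-violating (αⱼ loads on
a latent factor correlated with instrument strength |βxⱼ|, default
ρ = 0.5).  Planted outliers add a fixed shift on the same orientation.

Default effective sample sizes mirror the study design this emulates:
exposure 259,000 (a biobank questionnaire trait, ~90k cases/232k
controls), outcome 74,000 (a disease registry endpoint, ~22k cases/117k
controls), mediator 31,000; 21 instruments.  P-values are exact normal
tails; variants are spaced >20 Mb apart so default clumping keeps them
all; allele pairs are random and non-palindromic unless configured.

What the generator does **not** emulate: LD structure between instruments
(an LD matrix can be supplied externally), per-variant allele-frequency-
dependent SEs (a single c/√n scale is used — no estimator here consumes
EAF except for palindrome resolution), sample overlap between the two
GWAS, and selection of instruments from the same data that estimates
them (winner's curse).  Passing tests therefore validate the estimators
and plumbing, not robustness to those real-data features.

`simulate_mediation_triple` plants β2, β3 and a direct effect, gives the
mediator its own independent instruments, and reports all three GWAS on
the union of variants, so each leg's instrument selection operates exactly
as on real data.  With the default mediator sample size the exposure's
instruments stay sub-significant in the mediator GWAS, keeping the
mediator→outcome leg essentially uncontaminated.

## Calibration evidence and known limitations

`mrkit.studies` packages the replicated simulation studies the acceptance
tests run (problem sizes: 1,000 replicates at k=100 for IVW recovery,
2,000/500 for the Egger size/power, 200+200 at 1,000 simulations for
MR-PRESSO, 500 at k=100 for the weighted-median comparison; all seeded).

Measured characteristics worth knowing:

* Fixed-effects IVW at k=100 strong instruments, θ = 0.5: mean estimate
  ≈ 0.496 (≈1% attenuation from exposure measurement error) and 95% CI
  coverage ≈ 93–94%.
* The Egger intercept test is exactly calibrated when the NOME condition
  holds (size 5.2% with exposure error removed), but at the generator's
  realistic instrument strengths (I²_GX ≈ 0.95) slope attenuation leaks
  θ·mean(β̂x)·σx²/var(|β̂x|) into the intercept and inflates the size to
  ≈ 6–7% at τ = 0.005.  This is the known weak-instrument contamination
  of MR-Egger, shared by standard implementations; treat marginal
  intercept p-values with care when instruments are not very strong.
  Power against directional pleiotropy with μα = τ = 0.005 at k=100 is
  ≈ 97%.
* MR-PRESSO flags a planted 10×-effect outlier in ~100% of replicates and
  flags nothing in ≈ 97% of clean replicates.
* With 30% of instruments carrying same-sign pleiotropy, the weighted
  median's absolute bias is ≈ 0.3× the IVW bias.

Degenerate inputs: a single instrument degenerates IVW to its Wald ratio
with no heterogeneity result; Egger requires ≥3 and MR-PRESSO ≥4
instruments; β̂x exactly 0 drops the variant (ratio undefined); an
all-equal bootstrap yields SE 0 with a warning rather than an error;
β1 = 0 makes the proportion mediated undefined (NaN, flagged) while the
remaining decomposition fields are still returned.

The published odds ratios bundled in `mrkit.mediation` are inputs to the
decomposition arithmetic only.  Recomputing them would require the
original GWAS datasets, which are not bundled; nothing in the test suite
or the acceptance script claims to re-estimate them.
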