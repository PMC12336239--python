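# Methods

This note records the models, parameter choices and numerical decisions
behind `cardiomod`, and what the synthetic-data experiments do and do not
demonstrate.

## Study design being emulated

The pipeline targets a modifier-discovery setting: a small genome-sequenced
cohort (48 individuals, 6 families, 40 unrelated) ascertained for a shared
primary sarcomere variant, with three continuous cardiac traits (LVWT in mm,
EF in %, LVOTG in mmHg) measured within the cohort and case-control status
defined against ~100 external exome-sequenced controls.  Within-cohort
association analyses are restricted to unrelated individuals of the majority
ancestry with a hypertrophic diagnosis (28 in the default configuration);
relatedness is handled by this subset selection rather than a kinship model.
P-values at this scale rank genes; they are not genome-wide inference, and
the scoring algorithm treats them accordingly (a nominal 0.05 earns points;
nothing is multiplicity-corrected at the discovery stage).

## Filter cascade

Order: AVR quality → imputation → rarity → region blacklist → functional →
footprint construction.  Decisions taken where the rules leave room:

* AVR ≥ 0.02 inclusive (the score is a floor); quality is the one filter a
  whitelisted variant cannot escape.
* "In excess of 10 supporting reads" is strict (> 10); any alternate-allele
  read blocks imputation.
* Rarity (< 1%) and CADD (> 20) comparisons are strict; a population AF is
  either a value in [0, 1] or absent ("novel") — never encoded as 0.
* Whitelist membership (clinical/curated catalogues) rescues variants from
  the rarity, blacklist and functional filters.  Whether the original
  analysis applied the whitelist before or after blacklisting is not
  determinable; here precedence is explicit and configurable, and the
  default lets the whitelist win.
* Genic padding (5 kb) is applied to both ends of the full gene span, read
  as gene-region padding rather than TSS-only padding.
* Coordinates are 0-based half-open internally (BED); VCF positions are
  converted on read and multi-allelic records are split into biallelic ones.

## Association testing

The null model is ordinary least squares (continuous traits, with age, sex
and BMI) or logistic regression (case-control, unadjusted), fitted once per
trait via statsmodels.  Region tests consume 0/1/2 dosages with missing
genotypes mean-imputed per variant, weighted by the Beta(1, 25) density at
the in-sample MAF — the standard frequency-adaptive weighting; "adaptive
weighting" is interpreted as exactly this default.

**Mixture-of-chi-squares tails.**  The SKAT statistic's null distribution is
`Σ λ_j χ²₁`.  Tails are computed by: a closed form (one coefficient), smooth
1-D conditioning (two), Ruben's exact mixture-of-central-chi-squares series
(one-signed spectra, truncation error bounded by remaining mixture mass
< 1e-10), or Imhof's characteristic-function integration (mixed signs,
which only arise in the ratio-statistic path where spectra are large and the
integrand decays fast).  Liu's three-moment fit is the fallback and also
serves where speed matters inside the SKAT-O correction.

**Small-sample adjustment.**  At n = 28 the classical plug-in null
(estimated residual variance treated as known) is badly miscalibrated.  For
continuous traits the default evaluator instead treats the ratio `Q / r'r`,
which is free of the error variance under Gaussian errors: the event
{Q > c·r'r} is an indefinite quadratic form in the underlying errors and its
probability is computed exactly via the eigenvalues of
`(I−H)(K − cI)(I−H)`.  In simulation this gives empirical size ≈ 0.05 at
n = 28 (asserted to lie in [0.025, 0.075] over 2000 null replicates) where
the plug-in null deviates from a permutation reference by tens of Monte
Carlo standard errors.  A resampling switch
(`calibration="permutation"`) calibrates either test against residual
permutation; it is the validation route for the permutation-oracle contract
and the recommended route for markedly non-Gaussian traits.  The analytic
and permutation nulls condition on different information (the Gaussian law
vs the observed residual configuration), so for sparse genotype columns
they can legitimately differ by ~0.01 in absolute terms; a unit test bounds
this gap.

**SKAT-O.**  `Q_ρ = (1−ρ)Q_SKAT + ρQ_burden` over the default grid
{0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}.  The reported p corrects the
minimum per-ρ p by the standard decomposition onto the burden direction:
with score covariance `M`, burden projection `u = M1/m`, `s = 1'M1/m²`, the
common factor is `τ_ρ x` with `x ~ χ²₁`, the orthogonal part is a mixture
with the eigenvalues of `M − uu'/s`, and the cross term enters as a variance
inflation; the final probability is a 1-D integral over `x`.  Per-ρ
quantiles invert the Liu approximation in closed form.  Degenerate grids
short-circuit: {0} reproduces SKAT, {1} the collapsed burden test, exactly.
A double-permutation (min-p rank) calibration mirrors the analytic
combination under the resampling switch.

**Carrier tests.**  Continuous traits are median-dichotomized (values equal
to the median go low, "high" means strictly above); carriers per group are
compared by Fisher's exact test, two-sided by the point-probability method
(the sidedness is a flag), with per-group carrier frequencies and a pooled
two-proportion z for direction and magnitude.

**Case-control platform handling.**  Cases and controls are first restricted
to the padded exome-capture footprint; variant keys missing from one cohort
are homozygous reference there.  The post-test gene filter (paralog-family
prefixes OR, PRAME, MUC, … USP, plus a false-positive gene list) is applied
only to this genome-vs-exome comparison, where capture effects concentrate;
both lists are configurable because a naive prefix match also removes
legitimate genes (the DYN prefix hits the dynein heavy chain, for example).

## Modifier scoring

Strict comparisons throughout (p < 0.05, RPKM > 10, z > 3, Q < 0.01); absent
evidence scores 0, never negative; totals live in [−2, 12] and equal the sum
of the itemized points (asserted as properties).  The flagged −2 is applied
within scoring, independent of the association module's post-test filter.
Gene symbols are uppercased and stripped; alias resolution is an
input-preparation concern.  Ranking sorts by total, then smallest per-trait
p, then symbol.  Coexpression-network points require only membership at
Q < 0.01, not a direction of change.

## SV consensus

Reciprocal overlap is `min(shared/|a|, shared/|b|)`.  Clustering is single
linkage on the strict RO > 0.5 graph within (sample, type, chromosome); a
cluster is a consensus event if it spans ≥ 2 callers, or contains the
trusted caller.  The consensus interval is the union span (conservative;
intersection would also be defensible).  For the 20%-of-samples cap, events
from different samples count as the same SV when same-typed with RO > 0.5;
the cap is inclusive and is applied to consensus events, not raw calls.

## Expression follow-up

ΔCt = Ct(target) − Ct(housekeeping); ΔΔCt is referenced to the control-group
mean; fold = 2^−ΔΔCt.  Group comparison is a Welch t-test on ΔCt (the
log-scale, variance-stabilized quantity), not on fold changes, with BH
correction across genes; genes with fewer than two samples in a group are
skipped (listwise omission).  "Expressed" means mean FPKM > 1 in at least
one experimental arm.  Log-scale contrasts add a pseudo-count of 0.1 FPKM
before the ratio, since low-expression genes otherwise produce unstable or
undefined ratios.  The treatment analysis reports
log2[(treated/pre)/(sham/pre)], which cancels shared culture drift.

## Synthetic-data generator

The generator's defaults are the study conditions: 48 individuals, 6
families contributing 1–3 extra first-degree relatives (8 related in
total), sex 24/24, ancestry 34/7/3/2/2, morphology 30/6/3/3/2/2/1/1,
diagnoses 42/1/3/2.  Family ancestry/diagnosis assignments are
cross-classified by a small exact solver so that the number of unrelated
majority-ancestry hypertrophic probands equals the planted analysis-subset
size (28 by default; recorded on the cohort as fixture truth and preserved
proportionally under scaling).  Age/weight/height use the cohort's reported
summary statistics; LVWT (19 ± 5 mm), EF (62 ± 8 %) and LVOTG (25 ± 20 mmHg)
use typical HCM-clinic values, truncated at physiologic bounds (e.g. EF in
[5, 90]) by rejection sampling.  BMI is computed from weight and height.

Rare variants: MAF log-uniform on [1e-4, 0.01]; ~8 variants per gene
(1 + Poisson); founders draw binomial(2, MAF) genotypes; relatives inherit
each proband allele with probability 0.5.  A planted modifier gene assigns
carriers at the configured fraction, one heterozygous variant each; every
carried allele shifts the linked trait by the configured effect in trait-SD
units.  For case-control modifiers the effect is the log2 fold-enrichment of
carriers in cases relative to the background population frequency the
external controls are drawn from.  Planted modifier variants are annotated
as functional and rare/novel by construction — being functional rare
variants is the premise of a modifier in this framework, and without it
parameter-recovery runs would measure annotation luck rather than pipeline
behavior.  External controls are genotyped only at case variants inside the
exome footprint, emulating the platform bias the digital exome mitigates.
Missing genotypes are injected at 2% with Poisson(30) read depths consistent
with the true genotype, so the imputation rule operates on realistic
evidence.  External evidence tables give planted modifiers high expression,
LoF constraint and candidate status (4 points — deliberately below reporting
thresholds, so recovery additionally requires the association signal) and
null genes sub-threshold values.

What the generator does not emulate: read-level data, linkage
disequilibrium, realistic allele-frequency spectra outside the rare regime,
per-gene annotation error, or ancestry-differentiated allele frequencies.
Passing tests therefore demonstrate the pipeline's statistical behavior
under its own assumptions, not robustness to the full messiness of real
sequencing data.

## Problem sizes and runtime choices

Simulation-based checks use: 2000 replicates for the n = 28 type-I
contract; 500 null genes at the scaled cohort (n = 200, analysis subset
≈ 117) for distribution-level uniformity, where rare-variant p-values are
continuous — at n = 28 they are atomic (few carrier configurations), which
is precisely why the calibration contract at that size is a rejection rate,
not a KS statistic; 50 replicates at n = 200 for parameter recovery
(planted LVWT effect 1.5 SD, carrier fraction 0.3); and 200,000-draw
permutation oracles for the score tests, against implementations run with
600,000 internal resamples.  All randomness flows from explicit integer
seeds through `numpy.random.SeedSequence` substreams; fixed seeds give
byte-identical end-to-end outputs.

## Known limitations

* The analytic SKAT-O correction uses the plug-in score covariance (with
  the Liu quantile inversion); at very small n its p-values are
  approximate — the permutation switch is the reference there.
* Binary-trait SKAT uses the classical logistic score decomposition; it is
  well calibrated at the 128-sample case-control size used here but is not
  adjusted for very small or very unbalanced binary designs.
* The permutation calibration permutes residuals, which is exact for
  exchangeable designs (intercept-only) and approximate under covariates.
* SV consensus does no breakpoint refinement and never merges OTHER-typed
  calls with typed ones; single-linkage chains are resolved leftmost-first.
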