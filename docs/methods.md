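# Methods

This note documents the statistical model behind `tsmr`, the conventions
each estimator follows and why, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results at the last
digit.

## Setting

Two-sample Mendelian randomization estimates the causal effect θ of an
exposure on an outcome from GWAS summary statistics alone. For each
instrument SNP *j* we observe (β̂ₓⱼ, σₓⱼ) from the exposure GWAS and
(β̂ᵧⱼ, σᵧⱼ) from an outcome GWAS on a non-overlapping sample. Validity
requires each instrument to be (1) strongly associated with the exposure,
(2) independent of confounders, and (3) associated with the outcome only
through the exposure (exclusion restriction). Violations of (3) —
horizontal pleiotropy — are what the robust estimators and the sensitivity
battery are for.

The packaged example analysis treats three COVID-19 phenotypes (severity,
hospitalization, reported infection; COVID-19 Host Genetics Initiative
meta-analyses excluding UK Biobank) as exposures and ME/CFS (UK Biobank,
2,076 cases / 460,857 controls) as the outcome, with 20 / 24 / 13
pre-harmonized instruments respectively. These ship as checksummed TSVs and
drive the regression-test suite: the package reproduces the published
per-method estimates at print precision.

## Instrument preparation

**Selection** keeps SNPs with exposure association p strictly below the
threshold (default 5×10⁻⁸, the genome-wide convention).

**Clumping** is greedy: repeatedly keep the remaining SNP with the smallest
p-value (SNP id breaks ties, making the result independent of input order)
and discard all remaining SNPs with r² above the threshold (default 0.001)
against it or within the distance window (default 10,000 kb) on the same
chromosome. LD comes from a caller-supplied r² matrix rather than a
reference genotype panel: this keeps the operation deterministic and
self-contained, at the cost of requiring the caller to obtain LD estimates
for novel instrument sets.

**Harmonization** aligns outcome records to the exposure's effect allele,
flipping the outcome beta sign and complementing the allele frequency when
the coding is swapped, and recognizing strand flips through base
complementation. Palindromic SNPs (A/T, C/G) are dropped by default;
`infer_by_eaf` keeps them when both allele frequencies fall on the same side
of the (0.42, 0.58) ambiguity band — a conservative, commonly used window,
stated explicitly because no single standard exists. Non-complementary
allele mismatches are dropped with a recorded reason.

**Instrument strength.** Per-SNP variance explained is computed from the
association z-score, R² = z²/(z²+n−2); the commonly quoted
allele-frequency-bearing form 2·MAF(1−MAF)β² (for a standardized trait) is
algebraically close but requires a trustworthy allele frequency, which
public summary tables often lack, so the z-score form is the default and
the signature retains the MAF argument for validation. F follows as
(R²/(1−R²))·(n−m−1)/m with m = 1 for per-SNP F.

## Estimator conventions

The conventions below match the de-facto reference implementations in the
MR literature (the R TwoSampleMR/MendelianRandomization/MR-PRESSO
toolchain), verified digit-by-digit against the packaged example analysis.
Where a choice is conventional rather than forced, it is named here.

- **IVW.** Point estimate Σwβ̂ₓβ̂ᵧ/Σwβ̂ₓ², w = 1/σᵧ². Default SE is
  multiplicative random effects: fixed-effect SE times max(1, √(Q/(n−1))).
  The floor means the model never claims less uncertainty than the
  fixed-effect analysis; p-values are two-sided normal. A single-SNP set
  degenerates to the Wald ratio β̂ᵧ/β̂ₓ with SE σᵧ/|β̂ₓ|.
- **MR-Egger.** Pairs are first oriented so every β̂ₓ ≥ 0 (the fit is not
  invariant to allele-coding sign flips otherwise). WLS with intercept,
  weights 1/σᵧ²; both SEs divided by min(1, σ̂) — i.e. inflated when the
  fit is underdispersed — and tested against t(n−2). The unfloored t-test
  is available (`floor_dispersion=False`); it is the exactly calibrated
  version used in the calibration simulations, while the floored version is
  the reporting default because it is what published Egger tables use.
- **Weighted median.** Ratios sorted; cumulative weights taken at each
  observation's mass midpoint and normalized; linear interpolation at 0.5.
  Weights are inverse *delta-method* ratio variances
  σᵧ²/β̂ₓ² + β̂ᵧ²σₓ²/β̂ₓ⁴ — including the exposure-SE term matters at the
  fifth decimal and is required to reproduce published weighted-median
  values. SE from a parametric bootstrap (resample β̂ₓ, β̂ᵧ from their
  sampling normals, recompute the median with the original weights; default
  1000 replicates, seed recorded in the output metadata).
- **Modes.** Kernel density of the ratios with a normal kernel and the
  modified Silverman bandwidth 0.9·min(sd, MAD)/n^{1/5} (MAD scaled to the
  normal), multiplied by φ (default 1); inverse-variance weights for the
  weighted mode, equal weights for the simple mode. The density is
  evaluated the way R's `density()` evaluates it — 512 output points over
  [min−3h, max+3h], linear binning over a ±4h-padded range, FFT
  convolution (including R's kernel-grid spacing quirk), linear
  interpolation back — because published mode estimates sit on that grid:
  the argmax inherits its ~(range/511) discretization, and a
  mathematically cleaner dense-grid argmax differs from published values
  by one grid step. SE is the normal-scaled MAD of a seeded parametric
  bootstrap (robust to the mode jumping between clusters).
- **Odds ratios.** exp(β) with Wald CI exp(β ± z₁₋α/₂·σ), α = 0.05.
- Report tables round to 5 decimals; full precision is kept internally.

## Sensitivity battery

- **Cochran's Q** about the fixed-effect IVW fit (df n−1) or the Egger fit
  (df n−2), upper-tail chi-square p, no small-sample correction.
- **Egger intercept test**: intercept of the Egger fit against t(n−2).
- **MR-PRESSO.** Observed statistic: Σⱼ wⱼ(β̂ᵧⱼ − θ̂₋ⱼβ̂ₓⱼ)² where θ̂₋ⱼ is
  the IVW fit excluding SNP j. Null distribution: n_sim parametric datasets
  drawn under the leave-one-out fits; global p is the +1-continuity
  empirical exceedance (so p ∈ (0, 1] always). Per-SNP outlier p-values
  (same construction per residual) are Bonferroni-scaled by n and compared
  to 0.05; outlier testing runs when the global test is significant. With
  outliers removed, the corrected IVW is reported together with a
  distortion test: the observed relative shift between raw and corrected
  estimates compared against shifts from removing equally many random
  SNPs. n_sim defaults to 1000 and the seed is a required argument — the
  global p is a Monte-Carlo quantity with sd ≈ √(p(1−p)/n_sim) ≈ 0.016 at
  p ≈ 0.5, which is the tolerance regression tests should use.
- **Leave-one-out**: IVW re-fit without each SNP in turn plus the all-SNP
  row; a stable analysis keeps every row within a few full-model SEs.
- **Plot data**: forest (per-method β with CI), scatter (per-SNP effects
  with per-method fit lines), funnel (ratio vs precision with the IVW
  reference) as plain DataFrames; rendering is left to the caller.

## Synthetic-data generator

The generator emulates the post-clumping world the estimators assume:
independent instruments with true effects γⱼ (magnitudes uniform in a
configurable range, signs random or all-positive), outcome effects
θγⱼ + αⱼ, and observed summaries drawn as β̂ₓⱼ ~ N(γⱼ, σₓⱼ),
β̂ᵧⱼ ~ N(θγⱼ + αⱼ, σᵧⱼ) with σ = 1/√(2·eaf(1−eaf)·N) on each study's
sample-size scale. The pleiotropy term αⱼ is zero, balanced
N(0, sd) or directional N(mean, sd), optionally loaded on γⱼ to violate
the InSiDE assumption. Outlier contamination displaces a stated fraction
of outcome effects by a multiple of their SE, recorded in the ground
truth. Defaults (20 SNPs, exposure N = 750,000, outcome N = 460,000,
effect magnitudes 0.05–0.25) mirror the scale of the packaged analysis and
make every simulated instrument genome-wide significant by construction,
so selection thresholds remain meaningful on synthetic data.

Deliberately not emulated: LD between instruments (the analysis model
assumes post-clumping independence), case-control liability-scale effects
(betas are treated as exchangeable log-odds-scale quantities), allele-
frequency-dependent power, winner's-curse selection bias, and sample
overlap between the two GWAS. Passing simulation tests therefore
demonstrate correctness of the estimators under their own assumptions, not
robustness to those real-data complications.

Calibration checks use the exactly calibrated variants: the fixed-effect
IVW z-test and the unfloored Egger intercept t-test, both of which have
exact null distributions under the generator (outcome SEs are known). The
dispersion-floored reporting variants are conservative by construction, so
their rejection rates sit below nominal; testing the floored versions
against a nominal level would conflate convention with miscalibration.

Problem sizes used by the test suite: 1000 replicates at 50 SNPs for the
type-I-error and coverage checks, 500 replicates at 100 SNPs for Egger
pleiotropy recovery, 200 replicates at 10 SNPs (n_sim = 1000) for
MR-PRESSO outlier power, and 30 replicates each at 10/100/1000 SNPs for
the consistency check.

## Numerical and degenerate-input choices

- All weighted fits are closed-form normal equations in double precision;
  no iterative optimization anywhere.
- Wald ratio with β̂ₓ = 0 is an error ("null instrument"); mode bandwidth
  has a 10⁻⁸ floor so identical-ratio sets degenerate gracefully to the
  common ratio; a weighted median with over half the mass on an extreme
  ratio returns that ratio.
- p-values are clipped away from exact 0 (5e−324) so they remain in (0, 1].
- Greedy clumping ties on p-value break by SNP id; output sorts by
  (chromosome, position) with numeric chromosomes before non-numeric.
- Estimates on sets failing a method's preconditions (e.g. Egger with
  n < 3) are skipped in `estimate_all`, not fatal; direct calls raise.
- All bootstrap/simulation seeds are explicit arguments recorded in
  outputs; `estimate_all` derives per-method subseeds (seed + 1000·index)
  so methods are independently reproducible.

## Known limitations

- The published hospitalization IVW β is reproduced to ~6×10⁻⁷ but not to
  the 5×10⁻⁷ print half-ULP; the published table is internally
  inconsistent there (its own outlier-test row prints a different value
  for the same estimator, which this package matches to ~1×10⁻⁷). The
  remaining per-method entries reproduce at print precision from the
  shipped inputs.
- Bootstrap SEs (median/mode) and the PRESSO global p are Monte-Carlo
  quantities; they match published values only within Monte-Carlo
  tolerance since the original analyses did not record seeds.
- No multivariable MR, Steiger filtering, radial MR, or I²/Rucker model
  selection; no reference-panel clumping or liftover.
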