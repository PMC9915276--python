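# tsmr — two-sample Mendelian randomization from GWAS summary statistics

`tsmr` is a Python library for two-sample Mendelian randomization (TSMR):
causal inference that uses genetic variants as instrumental variables, with
the variant–exposure and variant–outcome associations taken from two
different GWAS. It covers the whole workflow — instrument selection and
strength statistics, harmonization of effect alleles, six causal-effect
estimators, and the standard sensitivity battery — and ships both a seeded
synthetic-data generator with known ground truth and a fully worked example
dataset: the published instrument sets relating COVID-19 severity,
hospitalization and susceptibility (COVID-19 Host Genetics Initiative) to
myalgic encephalomyelitis / chronic fatigue syndrome (ME/CFS, UK Biobank).

It is written for epidemiologists and statistical geneticists who want a
scriptable, reproducible TSMR analysis in Python with every stochastic step
seeded.

## The model

For instrument *j*, let β̂ₓⱼ (SE σₓⱼ) be its estimated effect on the exposure
and β̂ᵧⱼ (SE σᵧⱼ) its estimated effect on the outcome. If the instrument
assumptions hold, each Wald ratio β̂ᵧⱼ/β̂ₓⱼ estimates the causal effect θ.
The estimators combine the ratios under different robustness assumptions:

- **IVW** — θ̂ = Σwⱼβ̂ₓⱼβ̂ᵧⱼ / Σwⱼβ̂ₓⱼ², wⱼ = 1/σᵧⱼ²; equivalently the
  zero-intercept weighted regression of β̂ᵧ on β̂ₓ. The default is
  multiplicative random effects: the fixed-effect SE is scaled by the
  residual dispersion √(Q/(n−1)) floored at 1.
- **MR-Egger** — the same regression with a free intercept; the slope
  estimates θ, the intercept the average directional pleiotropy, both
  tested with t(n−2).
- **Weighted median** — the weighted 50th percentile of the ratios
  (weights = inverse delta-method ratio variances); consistent when ≥ 50%
  of the weight is on valid instruments.
- **Simple / weighted mode** — the argmax of a kernel-smoothed density of
  the ratios (modified-Silverman bandwidth); consistent when the largest
  homogeneous cluster is valid.
- **MR-PRESSO** — a simulation-based residual-sum-of-squares test that
  detects pleiotropic outlier SNPs and re-estimates without them.

Sensitivity: Cochran's Q about the IVW and Egger fits (heterogeneity), the
Egger intercept test (directional pleiotropy), leave-one-out re-estimation
(influence), and forest/scatter/funnel plot tables. Instrument strength is
summarized by R² = z²/(z²+n−2) and F = (R²/(1−R²))·(n−m−1)/m, with F > 10
the conventional weak-instrument bar.

## Worked example

```python
from tsmr import AnalysisConfig, run_analysis

bundle = run_analysis(AnalysisConfig(fixture="severity", seed=1))
print(bundle.estimates[["method", "nsnp", "beta", "se", "pval",
                        "or", "or_lo95", "or_hi95"]].round(5).to_string(index=False))
```

prints

```
         method  nsnp     beta      se    pval      or  or_lo95  or_hi95
       mr_egger    20 -0.00015 0.00083 0.85518 0.99985  0.99822  1.00148
weighted_median    20 -0.00044 0.00040 0.27808 0.99956  0.99878  1.00035
         ivw_re    20 -0.00027 0.00028 0.33277 0.99973  0.99917  1.00028
    simple_mode    20 -0.00057 0.00066 0.39050 0.99943  0.99814  1.00073
  weighted_mode    20 -0.00053 0.00049 0.28121 0.99947  0.99851  1.00043
      mr_presso    20 -0.00027 0.00028 0.33277 0.99973  0.99917  1.00028
```

Each row is one estimator applied to the 20 severity instruments: `beta` is
the estimated causal effect of (log-odds of) severe COVID-19 on ME/CFS risk,
`or` its odds-ratio scale with the 95% CI. Every CI straddles 1 and every
p-value is large, so no estimator detects a causal effect — the analysis's
substantive conclusion. `bundle.sensitivity` carries the Q tests, the Egger
intercept test and the MR-PRESSO global test (all non-significant here), and
`bundle.loo` the leave-one-out table.

The `examples/` directory has one short script per capability: the full
three-exposure analysis, ground-truth recovery on synthetic data, instrument
selection/clumping/strength, and outlier detection. A thin CLI wraps the
same pipeline:

```sh
tsmr run --fixture severity --seed 1 --out results/
tsmr simulate --n-snp 20 --theta 0.1 --seed 3 --out sim/
tsmr fixtures
```

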