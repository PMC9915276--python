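"""Full MR analysis of the packaged COVID-19 → ME/CFS instrument sets.

Runs all six estimators plus the sensitivity battery on each of the three
COVID-19 exposure phenotypes and prints report-shaped tables. Betas are on
the log-odds scale; an OR of 1.000 with a CI straddling 1 means no detectable
causal effect of that COVID-19 phenotype on ME/CFS risk.
"""

from tsmr import AnalysisConfig, combined_sensitivity_table, run_analysis

bundles = []
for name in ("severity", "hospitalization", "susceptibility"):
    bundle = run_analysis(AnalysisConfig(fixture=name, seed=1))
    bundles.append(bundle)
    print(f"\n=== COVID-19 {name} -> ME/CFS ===")
    print(
        bundle.estimates[["method", "nsnp", "beta", "se", "pval", "or", "or_lo95", "or_hi95"]]
        .round(5)
        .to_string(index=False)
    )

print("\n=== Sensitivity p-values (rows: test, columns: exposure) ===")
print(combined_sensitivity_table(bundles).round(3).to_string(index=False))
print(
    "\nNon-significant Q and Egger-intercept p-values mean the instruments are"
    "\nhomogeneous and show no directional pleiotropy; a non-significant PRESSO"
    "\nglobal test means no outlier SNP distorts the estimate."
)
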