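"""Case-control burden enrichment from alternative-allele counts.

The 2x2 table counts pDGV vs rare-synonymous alternative alleles in a
cancer and a control cohort over a fixed gene panel; a two-sided Fisher
exact test gives the odds ratio and p-value. Here the counts mimic an
80-patient cancer cohort against a larger control cohort with half the
per-subject pDGV rate (true OR = 2).
"""

from dgvar import ContingencyTable2x2, fisher_exact_two_sided
from dgvar.enrichment_stats import simulate_enrichment_coverage

table = ContingencyTable2x2(a=61, b=600, c=152, d=3000)
res = fisher_exact_two_sided(table, cancer_label="cancer", control_label="control")
print(f"odds ratio (cross-product) : {res.odds_ratio:.3f}")
print(f"odds ratio (cond. MLE)     : {res.odds_ratio_cmle:.3f}")
print(f"two-sided Fisher p         : {res.p_two_sided:.3g}")
print(f"95% CI                     : ({res.ci95[0]:.3f}, {res.ci95[1]:.3f})")
# OR ~2 with p << 0.05: the cancer cohort carries about twice the pDGV
# burden per rare synonymous allele.

cov = simulate_enrichment_coverage(n_replicates=500, true_or=2.0, seed=7)
print(f"CI coverage of true OR=2   : {100 * cov['coverage']:.1f}% over {cov['n_replicates']} replicates")
# Close to the nominal 95%: the interval is well calibrated at these counts.
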