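# dgvar

Deleterious germline variants shape cancer risk and, through the two-hit
model, tumor progression: a patient who inherits a truncated tumor
suppressor allele needs only one somatic event — loss of heterozygosity
(LOH), a second truncating mutation, or a copy-number loss — to fully
inactivate the gene. `dgvar` is a desk-scale pipeline for studying this in
tumor cohorts with matched germline and (serial) tumor sequencing:

1. **pDGV calling** — a filter cascade reduces raw germline VCF calls to
   *putative deleterious germline variants*: ClinVar pathogenic /
   likely-pathogenic variants (for cancer or unknown conditions), or
   protein-truncating variants (stop gain, frameshift) in tumor suppressor
   genes, surviving site quality ≥ 50, depth ≥ 10×, VAF ≥ 35% (removing
   CHIP-like sub-heterozygous calls), an SNV-cluster alignment-artifact
   rule (≥ 3 SNVs in 10 bp), population AF ≤ 1%, cohort recurrence ≤ 5%
   (platform artifacts), and a declarative manual-review exclusion list.
   Every variant carries a full per-filter trace.
2. **Burden enrichment** — a two-sided Fisher exact test on alternative
   allele counts (het = 1, hom = 2) of pDGVs vs rare synonymous variants
   (AF < 1%, same QC) between cancer and control cohorts on a pDGV gene
   panel, with cross-product and conditional-MLE odds ratios and a log-OR
   95% CI; plus a CADD-score comparison of pDGVs against a seeded
   20-per-patient background of truncating non-TSG variants.
3. **LOH in serial tumors** — forced allele counting at pDGV loci in each
   tumor, purity-corrected VAF (`clamp(VAF/purity, 0, 1)`), LOH at
   corrected tumor/normal ratio ≥ 1.6, a Kolmogorov–Smirnov comparison of
   TSG vs non-TSG corrected-VAF densities, and an exact Wilcoxon
   signed-rank test for deepening LOH in primary/metastatic pairs.
4. **Somatic consensus** — merge of four caller outputs (MuTect2, Strelka,
   VarScan, SomaticSniper; ≥ 2 callers required) plus hard filters: depth
   ≥ 10, alt reads ≥ 3, tumor VAF ≥ 5%, normal VAF ≤ 1%, dbSNP-unless-COSMIC,
   artifact blacklist.
5. **Germline–somatic interactions (GSIs)** — two-hit events in cis (pDGV +
   somatic truncation or CN loss in the same TSG) and in trans (pathways
   enriched by hypergeometric over-representation at p < 0.05 harboring
   both a germline and a role-consistent somatic hit), with per-patient
   private-GSI summaries across serial tumors.
6. **Synthetic cohorts** — a fully seeded generator emitting germline VCFs,
   annotation tables, gene roles, GMT pathways, purity-tagged tumor read
   counts with planted copy-neutral/deletion LOH, four caller VCFs per
   tumor, and a machine-readable truth table, so every stage can be tested
   against known ground truth.

The intended users are cancer-genomics methods developers and analysts who
want a reproducible, testable implementation of these analyses that runs on
plain text inputs (VCF, TSV, GMT, YAML) without protected data.

## Worked example

`examples/01_call_pdgvs.py` generates a 24-patient synthetic cohort and
runs the cascade:

```
input germline calls : 1193
pDGVs retained       : 31
removed per filter   :
  site_quality       24
  depth              24
  vaf                13
  snv_cluster        72
  pop_af             111
  classification     912
  cohort_recurrence  6
  exclusion_list     0
planted pDGVs        : 31
recovered / spurious : 31 / 0
```

The cascade retains exactly the 31 planted deleterious variants; the
removal counts sum to input − output (1193 − 31 = 1162), the filter-trace
conservation property. `examples/02_burden_enrichment.py` runs the burden
test on allele counts with a true rate ratio of 2:

```
odds ratio (cross-product) : 2.007
odds ratio (cond. MLE)     : 2.006
two-sided Fisher p         : 2.37e-05
95% CI                     : (1.472, 2.735)
CI coverage of true OR=2   : 94.6% over 500 replicates
```

The remaining examples cover LOH in serial tumors (`03`) and somatic
consensus + GSI detection (`04`). A thin CLI wraps the same library
(`dgvar simulate | call-pdgv | enrich | loh | gsi | report | run-all`).

## Layout

```
src/dgvar/
  io_cohort.py          VCF / annotation / GMT / manifest readers & writers
  dgvar_core.py         the pDGV filter cascade and rare-synonymous extraction
  enrichment_stats.py   allele counting, Fisher OR/CI, CADD comparison
  loh_analysis.py       purity correction, LOH calls, KS and signed-rank tests
  somatic_consensus.py  multi-caller merge and hard filters
  gsi_pathways.py       pathway score, hypergeometric ORA, gene/pathway GSIs
  synthetic_cohort.py   seeded cohort generator with planted truth
  pipeline.py, cli.py   orchestration and the command-line interface
docs/methods.md         models, assumptions, parameters, limitations
examples/               one narrative script per capability
```
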