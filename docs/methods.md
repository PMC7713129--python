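# Methods

## The pDGV filter cascade

A putative deleterious germline variant (pDGV) is a germline call that is
either (a) ClinVar pathogenic or likely pathogenic, where the reported
condition is cancer-related or unknown, or (b) protein-truncating (stop
gain or frameshift, judged on the canonical transcript — the protein-coding
transcript with the longest CDS — when annotated) in a curated tumor
suppressor gene, passing the population database's inbreeding-coefficient
and VQSR quality flags. ClinVar benign / likely-benign calls are never
pDGVs. By default ClinVar-pathogenic variants outside the TSG list are
retained (the definition is an OR); a `restrict_to_tsg` switch narrows it.

Both arms sit behind shared QC filters. The removal conditions are stated
as strict inequalities, so the retained region is the exact complement and
boundary values are kept:

| filter | removed when | retained boundary |
|---|---|---|
| site quality | < 50 (WCM) / < 30 (SPARK) | 50 / 30 |
| read depth | < 10× / < 8× | 10 / 8 |
| VAF | < 35% / < 20% | 0.35 / 0.20 |
| SNV cluster | ≥ 3 SNVs in any ≤ 10 bp window (WCM only) | — |
| population AF | > 1% | 0.01 |
| cohort recurrence | > 5% of patients | 0.05 |

The VAF floor removes sub-heterozygous calls compatible with clonal
hematopoiesis (CHIP); it is applied to SNVs and indels alike. The SNV
cluster rule is evaluated per sample (alignment artifacts are read-level
phenomena) and never flags indels. Cohort recurrence counts distinct
patients carrying the exact (chrom, pos, ref, alt) key; recurrent variants
are treated as platform artifacts. Manual-review steps become declarative
inputs: a `clinvar_condition_is_cancer` column and an exclusion-list file.

Every call receives an ordered trace of (filter, pass/fail). Retention
requires all passes; a removed call is attributed to its first failing
filter, which makes `input = output + Σ per-reason removals` an exact
invariant at every stage (checked in the run report).

Rare synonymous variants — the burden-test denominator — are synonymous
calls with population AF strictly below 1% passing the same QC filters.

Multiallelic VCF rows are decomposed into one record per alt allele with
depth equal to the sum of the AD field; genotypes 0/0 and ./. are dropped
at read time. A variant absent from the population database is treated as
novel (AF 0). Coordinates are 1-based VCF convention throughout.

## Burden enrichment

The 2×2 table counts alternative alleles (het = 1, hom-alt = 2) of pDGVs
vs rare synonymous variants in a cancer and a control cohort, restricted
to the panel of genes harboring pDGVs in the contributing cohorts, with
ethnicity matching realized as manifest-label subsetting. The p-value is
the two-sided Fisher exact test (scipy). Two odds ratios are emitted: the
sample cross-product (a·d)/(b·c), Haldane-corrected (+0.5 per cell) when
any cell is zero — the primary estimate — and the conditional MLE, the
convention of R's `fisher.test`, for comparability. The 95% CI uses the
normal approximation on the log cross-product OR. A Monte-Carlo harness
(Poisson cell counts at means with a known cross-product ratio, defaults
mirroring an 80-patient cancer cohort vs a 400-subject control cohort at
half the per-subject pDGV rate) verifies the CI's coverage is nominal.

The CADD comparison contrasts pDGV Phred scores against a seeded random
background of up to 20 protein-truncating non-TSG variants per patient.
Group sizes are unequal by construction, so the comparison uses an
unpaired exact rank-sum (Mann–Whitney) test; the paired signed-rank test
is reserved for genuinely paired analyses (primary vs metastatic VAFs).

## LOH in serial tumors

At each pDGV locus, reference/alternative read counts are taken in every
tumor of the patient (forced allele counting — no re-genotyping). The
tumor VAF is corrected for purity as `clamp(VAF / purity, 0, 1)`; the
normal VAF is not corrected (purity is a tumor property). LOH is called
when corrected-tumor / normal VAF ≥ 1.6, boundary inclusive. Tumors with
purity < 50% (or missing purity — the manifest carries the CLONET value
when available, else the pathology estimate) and loci with < 10 reads are
excluded first.

Background controls are protein-truncating variants in non-TSGs with
normal VAF in [0.35, 0.80] (heterozygous by definition). The TSG vs
control corrected-VAF densities are compared with a two-sided
Kolmogorov–Smirnov test (exact for small samples). Deepening LOH across
primary/metastatic pairs uses a two-sided Wilcoxon signed-rank test with
zero differences dropped; for ≤ 25 non-zero pairs the p-value is exact,
computed in-repo by a sign-flip dynamic program over the (tie-averaged,
doubled-to-integer) rank-sum distribution, since scipy's exact method does
not enumerate under ties. The two-sided p doubles the smaller tail, capped
at 1.

**Known limitation.** Dividing by purity inflates the VAF of *non-LOH*
heterozygous loci too (their raw VAF is ~0.5 at any purity, since all
cells carry the het), giving corrected ≈ 0.5/p and ratio ≈ 1/p. The
ratio-1.6 rule therefore only discriminates copy-neutral LOH from
heterozygosity when purity > 1/1.6 ≈ 0.625: at purity 0.5 every
heterozygous locus exceeds the threshold, and at 0.7 binomial read noise
at 85× still yields a ~20% false-positive rate. Sensitivity for planted
copy-neutral LOH is ≥ 95% at all purities ≥ 0.5; the false-positive rate
meets 5% only above ~0.75 purity. The acceptance suite states the
false-positive bound at purities 0.5/0.7/0.9 and the corresponding test
fails at the two lower purities by design of the correction formula — the
numbers are reported, not hidden. Analyses relying on low-purity tumors
should treat LOH calls below ~0.65 purity as unreliable.

## Somatic consensus and GSIs

Caller outputs are consumed as normalized per-caller VCFs (the callers are
never executed); indels appear only in Strelka/VarScan outputs. Variants
are aggregated by (tumor, locus) and kept when ≥ 2 callers agree; the
conjunctive hard filters (tumor depth ≥ 10, alt reads ≥ 3, tumor VAF ≥ 5%,
normal VAF ≤ 1%, dbSNP unless COSMIC, artifact blacklist) are
order-independent. Depth criteria apply to the tumor sample. Copy-number
events arrive as a gene-level TSV.

Gene-level GSIs require a pDGV and a somatic truncating mutation or
copy-number loss in the same TSG of the same patient's tumor. Pathway
GSIs build, per tumor, the union of germline pDGV genes and
role-consistent somatic genes (TSG: truncating or CN loss; oncogene:
non-truncating, non-synonymous), test each pathway with an upper-tail
hypergeometric over-representation test against a configurable universe
(default: all genes in the annotation table), and keep pathways with
p strictly below 0.05 that contain at least one germline and one somatic
hit. Pathways with identical gene sets (the same pathway from multiple
source collections) are merged. No multiple-testing correction is applied
at the stated threshold; Benjamini–Hochberg is available as an option.
The per-patient pathway score is `log10(1000·k/(m·K) + 1)` with k pathway
genes carrying DGVs, m patient genes carrying DGVs, K pathway genes.

The private-GSI fraction is computed over tumors of patients with ≥ 2
tumors (single-tumor patients cannot distinguish shared from private); a
tumor counts as private when it has at least one pathway GSI absent from
every other tumor of the same patient. This denominator choice is
configurable via the tumor census argument.

## Synthetic cohort generator

The generator emulates the statistical structure the cascade filters
against, not reads: sequencing depth is negative binomial with mean 85×
(the platform's average exome coverage; dispersion 30, giving SD ≈ 18),
het alt counts are binomial(depth, 0.5) conditioned into [0.38, 0.62] for
clean (non-boundary) plants, and site qualities are uniform in [60, 100].
Per patient it plants Poisson(1) pDGVs (70% TSG-truncating, 30% ClinVar),
25 truncating non-TSG background variants, 12 rare synonymous variants,
Poisson(0.5) CHIP-like decoys (VAF in (0.05, 0.35)), three single-rule QC
decoys and one 3-SNV cluster trio; cohort-wide it plants 12 common SNPs at
Hardy–Weinberg carrier rates with AF in (0.02, 0.5] and 3 artifact loci
carried by ~7.5% of samples. CADD scores are Normal(38, 3) for truncating
pDGVs vs Normal(32, 4) for background truncations — a deliberate planted
separation, so the CADD test demonstrates plumbing, not biology.

Tumor alt reads at a germline het are binomial with success probability
0.5 (no LOH), (1+p)/2 (copy-neutral LOH: tumor cells carry two alt
copies), or 1/(2−p) (hemizygous deletion retaining the alt allele: one alt
copy in tumor cells against two copies in admixed normal cells; both
limits check out — 0.5 as p→0, 1 as p→1). Both LOH models are generated so
the 1.6 threshold is exercised near and far from its boundary. LOH is
planted per (pDGV, tumor) with probability 0.5, +0.25 for metastatic
samples (the deepening structure). Tumor purities are uniform in
[0.5, 0.95], with one low-purity (0.42) and one missing-purity tumor
planted to exercise QC. Somatic callers detect each true variant
independently at their sensitivity (0.95 default) and add private
Poisson(2) false positives.

Every component draws from an integer-keyed RNG stream
`default_rng([seed, component, index])`, so output is byte-identical under
a fixed seed and adding patients does not shift earlier patients' draws.

What the generator does **not** emulate: linkage between variants, real
gene lengths and mutation spectra, mapping ambiguity (cluster decoys are
planted directly), subclonal somatic structure, CADD's actual score
distribution, or annotation errors. Passing tests therefore demonstrate
that the rules are implemented exactly and are well calibrated under the
stated read models — not that the pipeline's biological conclusions
transfer to any particular real cohort.

## Numerical choices and problem sizes

Exact small-sample methods are used where feasible: Fisher p by scipy's
exact routine (validated against full margin-preserving enumeration for
all tables with n ≤ 30), hypergeometric tail by `hypergeom.sf` (validated
against pmf summation for universes ≤ 50), KS by the exact method for
small samples (validated against the 70-split permutation distribution at
4 vs 4), signed-rank by in-repo sign-flip DP for n ≤ 25 (validated against
2^n enumeration for n ≤ 8). Degenerate inputs are defined, not crashed:
empty margins give p = 1 with the OR flagged undefined; all-tied score
sets give p = 1; all-zero paired differences give p = 1 with a warning;
zero normal VAF is an error (not a carried het). Calibration harnesses use
500 replicates/loci — enough for Monte-Carlo error of ~1–2 percentage
points on the reported rates while keeping the full test suite under a
few minutes on one CPU; the default end-to-end cohort is 40 patients
(~2,500 germline calls), which the cascade processes in seconds.
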