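"""Seeded generator of a complete synthetic tumor-cohort bundle.

Emulates the statistical structure the pipeline filters against: per-patient
germline VCFs with planted deleterious variants and several decoy classes,
a matching annotation table, gene roles, pathway gene sets, purity-tagged
tumor read counts at germline loci (with planted copy-neutral or deletion
LOH), four somatic-caller VCFs per tumor, gene-level copy-number events, a
YAML manifest and a machine-readable truth table.

Planted germline classes
------------------------
* ``pdgv_tsg_truncating`` / ``pdgv_clinvar`` — true positives. Clean,
  non-boundary attributes: quality in [60, 100], depth >= 30 (negative
  binomial around 85x, the platform's mean exome coverage), het VAF
  binomial conditioned into [0.38, 0.62], population AF < 0.005.
* ``common_snp`` — cohort-shared SNPs at population AF in (0.01, 0.5];
  carriers drawn per patient at Hardy-Weinberg carrier probability.
* ``chip_like`` — otherwise qualifying truncations at sub-heterozygous VAF
  in (0.05, 0.35), mimicking clonal hematopoiesis.
* ``low_quality`` — decoys violating exactly one QC rule each (site quality,
  depth, population-database QC flags, or a 3-SNVs-in-10bp cluster trio).
* ``artifact`` — loci recurring in > 5% of cohort samples.
* ``rare_synonymous`` — the burden-test denominator class.
* ``background_truncating_nonTSG`` — truncating variants outside TSGs
  (CADD/LOH control strata).

Tumor allele model
------------------
At a germline het locus with tumor purity p, alt reads are binomial with
success probability q: q = 0.5 without LOH; q = (1+p)/2 under copy-neutral
LOH (tumor cells carry 2 alt of 2 copies); q = 1/(2-p) under hemizygous
deletion with the alt allele retained (tumor cells carry 1 alt of 1 copy,
admixed normal cells 1 of 2).

Determinism: every component draws from its own integer-keyed RNG stream
``default_rng([seed, component, index])``, so the same seed reproduces the
bundle byte for byte and adding patients does not shift earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io_cohort import (
    CohortManifest,
    Patient,
    TumorSample,
    VariantCall,
    make_call,
    write_manifest,
    write_vcf,
)
from .somatic_consensus import CALLERS, SomaticCall

# RNG stream component ids
_C_LAYOUT = 0
_C_GERMLINE = 1
_C_TUMOR = 2
_C_SOMATIC = 3
_C_CALLER = 4

GERMLINE_CLASSES = (
    "pdgv_clinvar",
    "pdgv_tsg_truncating",
    "common_snp",
    "chip_like",
    "low_quality",
    "artifact",
    "rare_synonymous",
    "background_truncating_nonTSG",
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 40 patients, one expected pDGV per patient, 85x mean coverage
    (negative binomial, dispersion ``depth_shape``), tumor purity uniform in
    [0.5, 0.95], LOH probability 0.5 per (pDGV, tumor) with +0.25 for
    metastatic samples, artifacts planted in ~7.5% of samples.
    """

    seed: int
    n_patients: int = 40
    pdgv_rate: float = 1.0  # expected planted pDGVs per patient (Poisson)
    background_variants_per_patient: int = 25
    rare_synonymous_per_patient: int = 12
    low_quality_per_patient: int = 3
    cluster_trios_per_patient: int = 1
    chip_variant_rate: float = 0.5
    artifact_variant_count: int = 3
    artifact_carrier_fraction: float = 0.075  # > the 5% recurrence cap
    n_common_snps: int = 12
    common_snp_af_range: tuple[float, float] = (0.02, 0.5)
    depth_mean: float = 85.0
    depth_shape: float = 30.0  # negative-binomial dispersion
    purity_range: tuple[float, float] = (0.5, 0.95)
    two_tumor_fraction: float = 0.45
    loh_probability: float = 0.5
    met_loh_boost: float = 0.25
    copy_neutral_fraction: float = 0.7  # remaining LOH plants use deletion model
    somatic_per_tumor: int = 8
    somatic_decoys_per_tumor: int = 2
    cis_truncation_prob: float = 0.2  # somatic truncation hitting a pDGV gene
    cn_loss_prob: float = 0.12  # CN loss hitting a pDGV gene, per tumor
    caller_sensitivities: dict[str, float] = field(
        default_factory=lambda: {c: 0.95 for c in CALLERS}
    )
    caller_fp_rate: float = 2.0  # private false positives per caller per tumor
    n_tsg: int = 60
    n_oncogene: int = 20
    n_neutral: int = 120
    n_pathways: int = 12

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("a seed is required")
        for rate in (self.loh_probability, self.met_loh_boost, self.copy_neutral_fraction):
            if not 0.0 <= rate <= 1.0:
                raise InputError("rates must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth for every planted item."""

    variants: pd.DataFrame  # patient_id, chrom, pos, ref, alt, gene, class, genotype
    loh: pd.DataFrame  # patient_id, tumor_id, locus, loh_truth, model, expected_raw_vaf
    somatic: pd.DataFrame  # tumor_id, locus, gene, effect, expected_retained, decoy_reason

    def pdgv_truth(self) -> set[tuple[str, tuple]]:
        mask = self.variants["class"].isin(["pdgv_clinvar", "pdgv_tsg_truncating"])
        return {
            (r.patient_id, (r.chrom, int(r.pos), r.ref, r.alt))
            for r in self.variants[mask].itertuples(index=False)
        }


@dataclass
class CohortBundle:
    """Paths of a generated on-disk cohort."""

    root: Path
    manifest: Path
    germline_dir: Path
    annotations: Path
    gene_roles: Path
    pathways: Path
    tumor_observations: Path
    cn_events: Path
    caller_dir: Path
    exclusion_list: Path
    truth_variants: Path
    truth_loh: Path
    truth_somatic: Path


# ---------------------------------------------------------------------------
# Gene universe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Gene:
    name: str
    role: Optional[str]  # TSG | oncogene | None
    chrom: str
    start: int


def _build_genes(config: SimulationConfig) -> list[_Gene]:
    genes = []
    names = (
        [f"TSG{i:03d}" for i in range(1, config.n_tsg + 1)],
        [f"ONC{i:03d}" for i in range(1, config.n_oncogene + 1)],
        [f"NEU{i:03d}" for i in range(1, config.n_neutral + 1)],
    )
    roles = ("TSG", "oncogene", None)
    i = 0
    for group, role in zip(names, roles):
        for name in group:
            chrom = f"chr{(i % 22) + 1}"
            start = 1_000_000 * (1 + i // 22)
            genes.append(_Gene(name, role, chrom, start))
            i += 1
    return genes


class _LocusAllocator:
    """Deterministic, collision-free positions: 97 bp apart within a gene."""

    def __init__(self) -> None:
        self._next: dict[str, int] = {}

    def take(self, gene: _Gene, spacing: int = 97) -> int:
        k = self._next.get(gene.name, 0)
        self._next[gene.name] = k + 1
        return gene.start + spacing * k

    def take_cluster(self, gene: _Gene, size: int, gap: int = 4) -> list[int]:
        """Positions ``gap`` bp apart, placed past the regular allocations."""
        k = self._next.get(gene.name, 0)
        self._next[gene.name] = k + 1
        base = gene.start + 500_000 + 97 * k
        return [base + gap * j for j in range(size)]


# ---------------------------------------------------------------------------
# Read-count models
# ---------------------------------------------------------------------------

def _draw_depth(rng: np.random.Generator, mean: float, shape: float, minimum: int = 1) -> int:
    p = shape / (shape + mean)
    for _ in range(1000):
        d = int(rng.negative_binomial(shape, p))
        if d >= minimum:
            return d
    return minimum


def loh_allele_fraction(purity: float, loh: bool, model: str) -> float:
    """Expected alt-read fraction at a germline het locus in an admixed tumor."""
    if not loh:
        return 0.5
    if model == "copy_neutral":
        return (1.0 + purity) / 2.0
    if model == "deletion":
        return 1.0 / (2.0 - purity)
    raise InputError(f"unknown LOH model {model!r}")


def simulate_tumor_reads(
    purity: float,
    loh: bool,
    model: str,
    depth: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Binomial (ref_reads, alt_reads) at one germline het locus."""
    if not 0.0 < purity <= 1.0:
        raise InputError(f"purity {purity} outside (0, 1]")
    q = loh_allele_fraction(purity, loh, model)
    alt = int(rng.binomial(depth, q))
    return depth - alt, alt


def simulate_caller_detection(
    calls: Sequence[SomaticCall],
    sensitivities: dict[str, float],
    rng: np.random.Generator,
    fp_rate: float = 0.0,
    fp_factory=None,
) -> dict[str, list[SomaticCall]]:
    """Per-caller detected subsets of ``calls`` plus private false positives.

    Each variant appears in each caller's output independently with that
    caller's sensitivity; indels are only detectable by Strelka and VarScan.
    ``fp_factory(rng, caller, i)`` builds the i-th private false positive for
    a caller (Poisson ``fp_rate`` count each).
    """
    from dataclasses import replace

    out: dict[str, list[SomaticCall]] = {c: [] for c in sensitivities}
    for call in calls:
        eligible = (
            ("strelka", "varscan") if call.is_indel else tuple(sensitivities)
        )
        for caller in sensitivities:
            if caller in eligible and rng.random() < sensitivities[caller]:
                out[caller].append(replace(call, callers=frozenset({caller})))
    if fp_rate > 0 and fp_factory is not None:
        for caller in sensitivities:
            for i in range(int(rng.poisson(fp_rate))):
                out[caller].append(fp_factory(rng, caller, i))
    return out


# ---------------------------------------------------------------------------
# Germline planting
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(4, size=2, replace=False)
    return str(_BASES[i]), str(_BASES[j])


def _indel_alleles(rng: np.random.Generator) -> tuple[str, str]:
    base, ins = _snv_alleles(rng)
    if rng.random() < 0.5:
        return base, base + ins  # insertion
    return base + ins, base  # deletion


def _het_alt(rng: np.random.Generator, depth: int) -> int:
    # binomial het conditioned well inside the 0.35 VAF boundary
    for _ in range(1000):
        alt = int(rng.binomial(depth, 0.5))
        if 0.38 <= alt / depth <= 0.62:
            return alt
    return depth // 2


@dataclass
class _Planted:
    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    klass: str
    call: VariantCall
    annotation: dict


def _annotation_row(
    gene: _Gene,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    effect: str,
    clinvar_class: str = "absent",
    condition_is_cancer: str = "unknown",
    pop_af: float = 0.0,
    inbreeding_pass: bool = True,
    vqsr_pass: bool = True,
    cadd: Optional[float] = None,
    dbsnp: bool = False,
    cosmic: bool = False,
) -> dict:
    return {
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gene": gene.name,
        "effect": effect,
        "canonical_effect": effect,
        "clinvar_class": clinvar_class,
        "clinvar_condition_is_cancer": condition_is_cancer,
        "pop_af": round(pop_af, 6),
        "inbreeding_pass": inbreeding_pass,
        "vqsr_pass": vqsr_pass,
        "cadd_phred": round(cadd, 2) if cadd is not None else "",
        "dbsnp": dbsnp,
        "cosmic": cosmic,
    }


def _plant_germline(
    config: SimulationConfig,
    genes: list[_Gene],
    alloc: _LocusAllocator,
) -> tuple[list[_Planted], list[dict]]:
    """All per-patient and cohort-level germline plants + annotation rows."""
    tsgs = [g for g in genes if g.role == "TSG"]
    non_tsgs = [g for g in genes if g.role != "TSG"]
    all_genes = genes
    planted: list[_Planted] = []
    annotations: dict[tuple, dict] = {}
    patient_ids = [f"P{i + 1:03d}" for i in range(config.n_patients)]

    layout_rng = np.random.default_rng([config.seed, _C_LAYOUT])

    # --- cohort-level common SNPs -------------------------------------------
    common = []
    for _ in range(config.n_common_snps):
        g = all_genes[int(layout_rng.integers(len(all_genes)))]
        pos = alloc.take(g)
        ref, alt = _snv_alleles(layout_rng)
        af = float(layout_rng.uniform(*config.common_snp_af_range))
        effect = "missense" if layout_rng.random() < 0.5 else "synonymous"
        common.append((g, pos, ref, alt, af, effect))
        annotations[(g.chrom, pos, ref, alt)] = _annotation_row(
            g, g.chrom, pos, ref, alt, effect, pop_af=af, dbsnp=True
        )

    # --- cohort-level platform artifacts ------------------------------------
    n_carriers = max(2, math.ceil(config.artifact_carrier_fraction * config.n_patients))
    artifacts = []
    for _ in range(config.artifact_variant_count):
        g = tsgs[int(layout_rng.integers(len(tsgs)))]
        pos = alloc.take(g)
        ref, alt = _snv_alleles(layout_rng)
        carriers = sorted(
            layout_rng.choice(config.n_patients, size=n_carriers, replace=False).tolist()
        )
        artifacts.append((g, pos, ref, alt, carriers))
        annotations[(g.chrom, pos, ref, alt)] = _annotation_row(
            g, g.chrom, pos, ref, alt, "stop_gained", cadd=35.0
        )

    # --- per-patient plants ---------------------------------------------------
    for i, pid in enumerate(patient_ids):
        rng = np.random.default_rng([config.seed, _C_GERMLINE, i])

        def clean_call(pos_gene: _Gene, pos: int, ref: str, alt: str, genotype: str = "het"):
            depth = _draw_depth(rng, config.depth_mean, config.depth_shape, minimum=30)
            if genotype == "hom_alt":
                alt_depth = depth - int(rng.binomial(depth, 0.01))
            else:
                alt_depth = _het_alt(rng, depth)
            qual = round(float(rng.uniform(60, 100)), 1)
            return make_call(pid, pos_gene.chrom, pos, ref, alt, qual, depth, alt_depth, genotype)

        # pDGVs
        n_pdgv = int(rng.poisson(config.pdgv_rate))
        pdgv_genes = rng.choice(len(tsgs), size=min(n_pdgv, len(tsgs)), replace=False)
        for gi in pdgv_genes:
            g = tsgs[int(gi)]
            if rng.random() < 0.7:
                klass = "pdgv_tsg_truncating"
                if rng.random() < 0.6:
                    ref, alt = _snv_alleles(rng)
                    effect = "stop_gained"
                else:
                    ref, alt = _indel_alleles(rng)
                    effect = "frameshift"
                clinvar = "vus" if rng.random() < 0.3 else "absent"
                cadd = float(np.clip(rng.normal(38, 3), 20, 60))
            else:
                klass = "pdgv_clinvar"
                ref, alt = _snv_alleles(rng)
                effect = "missense"
                clinvar = "pathogenic" if rng.random() < 0.6 else "likely_pathogenic"
                cadd = float(np.clip(rng.normal(33, 4), 15, 60))
            pos = alloc.take(g)
            call = clean_call(g, pos, ref, alt)
            condition = "true" if rng.random() < 0.5 else "unknown"
            ann = _annotation_row(
                g, g.chrom, pos, ref, alt, effect,
                clinvar_class=clinvar,
                condition_is_cancer=condition,
                pop_af=float(rng.uniform(0, 0.005)),
                cadd=cadd,
            )
            annotations[(g.chrom, pos, ref, alt)] = ann
            planted.append(_Planted(pid, g.chrom, pos, ref, alt, g.name, klass, call, ann))

        # background truncating non-TSG variants (CADD / LOH controls)
        for _ in range(config.background_variants_per_patient):
            g = non_tsgs[int(rng.integers(len(non_tsgs)))]
            pos = alloc.take(g)
            if rng.random() < 0.6:
                ref, alt = _snv_alleles(rng)
                effect = "stop_gained"
            else:
                ref, alt = _indel_alleles(rng)
                effect = "frameshift"
            call = clean_call(g, pos, ref, alt)
            ann = _annotation_row(
                g, g.chrom, pos, ref, alt, effect,
                pop_af=float(rng.uniform(0, 0.008)),
                cadd=float(np.clip(rng.normal(32, 4), 10, 60)),
            )
            annotations[(g.chrom, pos, ref, alt)] = ann
            planted.append(
                _Planted(pid, g.chrom, pos, ref, alt, g.name, "background_truncating_nonTSG", call, ann)
            )

        # rare synonymous variants
        for _ in range(config.rare_synonymous_per_patient):
            g = all_genes[int(rng.integers(len(all_genes)))]
            pos = alloc.take(g)
            ref, alt = _snv_alleles(rng)
            genotype = "hom_alt" if rng.random() < 0.1 else "het"
            call = clean_call(g, pos, ref, alt, genotype)
            ann = _annotation_row(
                g, g.chrom, pos, ref, alt, "synonymous",
                pop_af=float(rng.uniform(0, 0.008)),
            )
            annotations[(g.chrom, pos, ref, alt)] = ann
            planted.append(_Planted(pid, g.chrom, pos, ref, alt, g.name, "rare_synonymous", call, ann))

        # CHIP-like: qualifying truncation at sub-heterozygous VAF
        for _ in range(int(rng.poisson(config.chip_variant_rate))):
            g = tsgs[int(rng.integers(len(tsgs)))]
            pos = alloc.take(g)
            ref, alt = _snv_alleles(rng)
            depth = _draw_depth(rng, config.depth_mean, config.depth_shape, minimum=30)
            vaf = float(rng.uniform(0.07, 0.30))
            alt_depth = min(max(int(round(vaf * depth)), max(1, int(0.06 * depth) + 1)),
                            int(0.34 * depth))
            qual = round(float(rng.uniform(60, 100)), 1)
            call = make_call(pid, g.chrom, pos, ref, alt, qual, depth, alt_depth, "het")
            ann = _annotation_row(g, g.chrom, pos, ref, alt, "stop_gained", cadd=36.0)
            annotations[(g.chrom, pos, ref, alt)] = ann
            planted.append(_Planted(pid, g.chrom, pos, ref, alt, g.name, "chip_like", call, ann))

        # low-quality decoys: each violates exactly one QC rule
        subtypes = ("low_quality_score", "low_depth", "exac_qc_fail")
        for k in range(config.low_quality_per_patient):
            subtype = subtypes[k % len(subtypes)]
            g = tsgs[int(rng.integers(len(tsgs)))]
            pos = alloc.take(g)
            ref, alt = _snv_alleles(rng)
            depth = _draw_depth(rng, config.depth_mean, config.depth_shape, minimum=30)
            qual = round(float(rng.uniform(60, 100)), 1)
            inbreeding = vqsr = True
            if subtype == "low_quality_score":
                qual = round(float(rng.uniform(20, 45)), 1)
            elif subtype == "low_depth":
                depth = int(rng.integers(3, 9))
            else:
                if rng.random() < 0.5:
                    inbreeding = False
                else:
                    vqsr = False
            alt_depth = _het_alt(rng, depth) if depth >= 10 else max(1, depth // 2)
            call = make_call(pid, g.chrom, pos, ref, alt, qual, depth, alt_depth, "het")
            ann = _annotation_row(
                g, g.chrom, pos, ref, alt, "stop_gained",
                inbreeding_pass=inbreeding, vqsr_pass=vqsr, cadd=35.0,
            )
            annotations[(g.chrom, pos, ref, alt)] = ann
            planted.append(_Planted(pid, g.chrom, pos, ref, alt, g.name, "low_quality", call, ann))

        # SNV cluster trios (alignment-artifact decoys; violate only the cluster rule)
        for _ in range(config.cluster_trios_per_patient):
            g = tsgs[int(rng.integers(len(tsgs)))]
            positions = alloc.take_cluster(g, size=3, gap=4)
            for pos in positions:
                ref, alt = _snv_alleles(rng)
                call = clean_call(g, pos, ref, alt)
                ann = _annotation_row(g, g.chrom, pos, ref, alt, "stop_gained", cadd=35.0)
                annotations[(g.chrom, pos, ref, alt)] = ann
                planted.append(_Planted(pid, g.chrom, pos, ref, alt, g.name, "low_quality", call, ann))

        # cohort-level plants realized in this patient
        for g, pos, ref, alt, af, effect in common:
            p_carrier = 1.0 - (1.0 - af) ** 2
            if rng.random() < p_carrier:
                genotype = "hom_alt" if rng.random() < af else "het"
                call = clean_call(g, pos, ref, alt, genotype)
                planted.append(_Planted(pid, g.chrom, pos, ref, alt, g.name, "common_snp", call,
                                        annotations[(g.chrom, pos, ref, alt)]))
        for g, pos, ref, alt, carriers in artifacts:
            if i in carriers:
                call = clean_call(g, pos, ref, alt)
                planted.append(_Planted(pid, g.chrom, pos, ref, alt, g.name, "artifact", call,
                                        annotations[(g.chrom, pos, ref, alt)]))

    return planted, list(annotations.values())


# ---------------------------------------------------------------------------
# Bundle generation
# ---------------------------------------------------------------------------

def _make_manifest(config: SimulationConfig) -> CohortManifest:
    patients = []
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, _C_TUMOR, i, 0])
        pid = f"P{i + 1:03d}"
        tumors = [TumorSample(f"{pid}_T1", "primary",
                              round(float(rng.uniform(*config.purity_range)), 3))]
        if rng.random() < config.two_tumor_fraction:
            tumors.append(TumorSample(f"{pid}_T2", "metastatic",
                                      round(float(rng.uniform(*config.purity_range)), 3)))
        # exercise the purity QC: one low-purity and one missing-purity tumor
        if i == 0:
            tumors[0].purity = 0.42
        if i == 1:
            tumors[0].purity = None
        ethnicity = "EUR" if rng.random() < 0.7 else "AJ"
        patients.append(Patient(pid, ethnicity, f"{pid}_germline", tumors))
    return CohortManifest(patients=patients, filter_profile="wcm")


def generate_cohort(config: SimulationConfig, out_dir: str | Path) -> tuple[CohortBundle, TruthTable]:
    """Write a complete cohort bundle to a fresh directory; return its truth."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise InputError(f"output directory {out} is not empty")
    (out / "germline").mkdir(parents=True, exist_ok=True)
    (out / "callers").mkdir(exist_ok=True)

    genes = _build_genes(config)
    alloc = _LocusAllocator()
    planted, annotation_rows = _plant_germline(config, genes, alloc)
    manifest = _make_manifest(config)

    # germline VCFs
    by_patient: dict[str, list[VariantCall]] = {p.patient_id: [] for p in manifest.patients}
    for pv in planted:
        by_patient[pv.patient_id].append(pv.call)
    for patient in manifest.patients:
        write_vcf(
            by_patient[patient.patient_id],
            out / "germline" / f"{patient.patient_id}.vcf",
            patient.germline_sample,
        )

    # tumor observations + LOH truth
    obs_rows, loh_rows = _plant_tumors(config, manifest, planted)

    # somatic truth + caller VCFs + CN events
    somatic_rows, cn_rows, somatic_annotation_rows = _plant_somatic(
        config, manifest, planted, genes, alloc, out / "callers"
    )
    annotation_rows = annotation_rows + somatic_annotation_rows

    ann_df = pd.DataFrame(annotation_rows).sort_values(
        ["chrom", "pos", "ref", "alt"], kind="mergesort"
    )
    ann_df.to_csv(out / "annotations.tsv", sep="\t", index=False)

    role_rows = [{"gene": g.name, "role": g.role} for g in genes if g.role]
    pd.DataFrame(role_rows).to_csv(out / "gene_roles.tsv", sep="\t", index=False)

    _write_pathways(config, genes, out / "pathways.gmt")

    obs_df = pd.DataFrame(obs_rows)
    obs_df.to_csv(out / "tumor_observations.tsv", sep="\t", index=False)
    pd.DataFrame(cn_rows, columns=["tumor_id", "gene", "direction"]).to_csv(
        out / "cn_events.tsv", sep="\t", index=False
    )
    write_manifest(manifest, out / "manifest.yaml")
    with open(out / "exclusion_list.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")

    truth = TruthTable(
        variants=pd.DataFrame(
            [
                {
                    "patient_id": pv.patient_id,
                    "chrom": pv.chrom,
                    "pos": pv.pos,
                    "ref": pv.ref,
                    "alt": pv.alt,
                    "gene": pv.gene,
                    "class": pv.klass,
                    "genotype": pv.call.genotype,
                }
                for pv in planted
            ]
        ),
        loh=pd.DataFrame(loh_rows),
        somatic=pd.DataFrame(somatic_rows),
    )
    truth.variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    truth.loh.to_csv(out / "truth_loh.tsv", sep="\t", index=False)
    truth.somatic.to_csv(out / "truth_somatic.tsv", sep="\t", index=False)

    bundle = CohortBundle(
        root=out,
        manifest=out / "manifest.yaml",
        germline_dir=out / "germline",
        annotations=out / "annotations.tsv",
        gene_roles=out / "gene_roles.tsv",
        pathways=out / "pathways.gmt",
        tumor_observations=out / "tumor_observations.tsv",
        cn_events=out / "cn_events.tsv",
        caller_dir=out / "callers",
        exclusion_list=out / "exclusion_list.tsv",
        truth_variants=out / "truth_variants.tsv",
        truth_loh=out / "truth_loh.tsv",
        truth_somatic=out / "truth_somatic.tsv",
    )
    return bundle, truth


def _plant_tumors(config, manifest, planted):
    obs_rows = []
    loh_rows = []
    for i, patient in enumerate(manifest.patients):
        rng = np.random.default_rng([config.seed, _C_TUMOR, i, 1])
        pid = patient.patient_id
        pdgvs = [
            pv for pv in planted
            if pv.patient_id == pid
            and pv.klass in ("pdgv_clinvar", "pdgv_tsg_truncating")
            and pv.call.genotype == "het"
        ]
        controls = [
            pv for pv in planted
            if pv.patient_id == pid
            and pv.klass == "background_truncating_nonTSG"
            and pv.call.genotype == "het"
        ]
        for pv in pdgvs:
            model = "copy_neutral" if rng.random() < config.copy_neutral_fraction else "deletion"
            for tumor in patient.tumors:
                p_loh = config.loh_probability
                if tumor.site == "metastatic":
                    p_loh = min(1.0, p_loh + config.met_loh_boost)
                loh = bool(rng.random() < p_loh)
                depth = _draw_depth(rng, config.depth_mean, config.depth_shape, minimum=1)
                purity = tumor.purity if tumor.purity is not None else 0.7
                ref_reads, alt_reads = simulate_tumor_reads(purity, loh, model, depth, rng)
                obs_rows.append({
                    "tumor_id": tumor.tumor_id, "patient_id": pid, "site": tumor.site,
                    "chrom": pv.chrom, "pos": pv.pos, "ref": pv.ref, "alt": pv.alt,
                    "ref_reads": ref_reads, "alt_reads": alt_reads,
                })
                loh_rows.append({
                    "patient_id": pid, "tumor_id": tumor.tumor_id,
                    "chrom": pv.chrom, "pos": pv.pos, "ref": pv.ref, "alt": pv.alt,
                    "loh_truth": loh, "model": model,
                    "expected_raw_vaf": round(loh_allele_fraction(purity, loh, model), 4),
                })
        for pv in controls:
            for tumor in patient.tumors:
                depth = _draw_depth(rng, config.depth_mean, config.depth_shape, minimum=1)
                purity = tumor.purity if tumor.purity is not None else 0.7
                ref_reads, alt_reads = simulate_tumor_reads(purity, False, "copy_neutral", depth, rng)
                obs_rows.append({
                    "tumor_id": tumor.tumor_id, "patient_id": pid, "site": tumor.site,
                    "chrom": pv.chrom, "pos": pv.pos, "ref": pv.ref, "alt": pv.alt,
                    "ref_reads": ref_reads, "alt_reads": alt_reads,
                })
    return obs_rows, loh_rows


_CALLER_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=TDP,Number=1,Type=Integer,Description="Tumor read depth">
##INFO=<ID=TAD,Number=1,Type=Integer,Description="Tumor alt-supporting reads">
##INFO=<ID=NVAF,Number=1,Type=Float,Description="Normal VAF">
##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP member">
##INFO=<ID=COS,Number=0,Type=Flag,Description="COSMIC member">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_caller_vcf(calls: Sequence[SomaticCall], path: Path) -> None:
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    chroms = sorted({c.chrom for c in calls})
    contigs = "".join(f"##contig=<ID={ch}>\n" for ch in chroms)
    with open(path, "w") as fh:
        fh.write(_CALLER_VCF_HEADER.format(contigs=contigs))
        for c in calls:
            info = f"TDP={c.tumor_depth};TAD={c.tumor_alt};NVAF={c.normal_vaf:.4f}"
            if c.dbsnp:
                info += ";DB"
            if c.cosmic:
                info += ";COS"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t.\t{info}\n")


def _plant_somatic(config, manifest, planted, genes, alloc, caller_dir: Path):
    somatic_rows = []
    cn_rows = []
    ann_rows: dict[tuple, dict] = {}
    gene_by_name = {g.name: g for g in genes}
    tsgs = [g for g in genes if g.role == "TSG"]
    oncs = [g for g in genes if g.role == "oncogene"]
    neus = [g for g in genes if g.role is None]

    for i, patient in enumerate(manifest.patients):
        rng = np.random.default_rng([config.seed, _C_SOMATIC, i])
        pid = patient.patient_id
        pdgv_genes = sorted({
            pv.gene for pv in planted
            if pv.patient_id == pid and pv.klass in ("pdgv_clinvar", "pdgv_tsg_truncating")
        })
        for tumor in patient.tumors:
            true_calls: list[SomaticCall] = []

            def add_call(g: _Gene, effect: str, decoy: Optional[str] = None):
                pos = alloc.take(g)
                if effect == "frameshift":
                    ref, alt = _indel_alleles(rng)
                else:
                    ref, alt = _snv_alleles(rng)
                depth = _draw_depth(rng, config.depth_mean, config.depth_shape, minimum=20)
                vaf = float(rng.uniform(0.1, 0.6))
                alt_reads = max(3, int(round(vaf * depth)))
                normal_vaf = float(rng.uniform(0, 0.008))
                dbsnp = cosmic = False
                if decoy == "dbsnp_not_cosmic":
                    dbsnp, cosmic = True, False
                elif decoy == "low_alt":
                    alt_reads = 2
                elif decoy == "high_normal_vaf":
                    normal_vaf = float(rng.uniform(0.03, 0.10))
                elif decoy == "low_tumor_vaf":
                    alt_reads = max(3, int(0.03 * depth))
                call = SomaticCall(
                    tumor_id=tumor.tumor_id, chrom=g.chrom, pos=pos, ref=ref, alt=alt,
                    callers=frozenset(CALLERS), tumor_depth=depth, tumor_alt=alt_reads,
                    normal_vaf=round(normal_vaf, 4), dbsnp=dbsnp, cosmic=cosmic,
                )
                true_calls.append(call)
                ann_rows[(g.chrom, pos, ref, alt)] = _annotation_row(
                    g, g.chrom, pos, ref, alt, effect, dbsnp=dbsnp, cosmic=cosmic
                )
                somatic_rows.append({
                    "tumor_id": tumor.tumor_id, "chrom": g.chrom, "pos": pos,
                    "ref": ref, "alt": alt, "gene": g.name, "effect": effect,
                    "expected_retained": decoy is None,
                    "decoy_reason": decoy or "",
                })

            # cis hits on the patient's pDGV genes (gene-level GSIs)
            for gene_name in pdgv_genes:
                g = gene_by_name[gene_name]
                if rng.random() < config.cis_truncation_prob:
                    add_call(g, "stop_gained")
                if rng.random() < config.cn_loss_prob:
                    cn_rows.append({"tumor_id": tumor.tumor_id, "gene": gene_name,
                                    "direction": "loss"})

            # background somatic landscape (role-consistent effects)
            for _ in range(config.somatic_per_tumor):
                u = rng.random()
                if u < 0.4:
                    g = tsgs[int(rng.integers(len(tsgs)))]
                    effect = "stop_gained" if rng.random() < 0.7 else "frameshift"
                elif u < 0.7:
                    g = oncs[int(rng.integers(len(oncs)))]
                    effect = "missense"
                else:
                    g = neus[int(rng.integers(len(neus)))]
                    effect = "missense"
                add_call(g, effect)

            # filter decoys (survive consensus, fail the hard filters)
            decoy_kinds = ("dbsnp_not_cosmic", "low_alt", "high_normal_vaf", "low_tumor_vaf")
            for k in range(config.somatic_decoys_per_tumor):
                g = neus[int(rng.integers(len(neus)))]
                add_call(g, "missense", decoy=decoy_kinds[k % len(decoy_kinds)])

            # caller outputs, with private false positives
            def fp_factory(fp_rng, caller, _k):
                g = neus[int(fp_rng.integers(len(neus)))]
                pos = alloc.take(g)
                ref, alt = _snv_alleles(fp_rng)
                depth = _draw_depth(fp_rng, config.depth_mean, config.depth_shape, minimum=20)
                return SomaticCall(
                    tumor_id=tumor.tumor_id, chrom=g.chrom, pos=pos, ref=ref, alt=alt,
                    callers=frozenset({caller}), tumor_depth=depth,
                    tumor_alt=max(3, int(0.3 * depth)),
                    normal_vaf=0.0,
                )

            per_caller = simulate_caller_detection(
                true_calls, config.caller_sensitivities, rng,
                fp_rate=config.caller_fp_rate, fp_factory=fp_factory,
            )
            for caller, calls in per_caller.items():
                write_caller_vcf(calls, caller_dir / f"{tumor.tumor_id}.{caller}.vcf")

    return somatic_rows, cn_rows, list(ann_rows.values())


_PATHWAY_THEMES = (
    "DNA_REPAIR", "TP53_REGULATION", "HIPPO_SIGNALING", "WNT_SIGNALING",
    "TCR_SIGNALING", "CELL_CYCLE", "APOPTOSIS", "CHROMATIN_REMODELING",
    "PI3K_AKT", "RTK_RAS", "NOTCH_SIGNALING", "TGF_BETA",
)


def _write_pathways(config: SimulationConfig, genes: list[_Gene], path: Path) -> None:
    rng = np.random.default_rng([config.seed, _C_LAYOUT, 1])
    names = [
        _PATHWAY_THEMES[i] if i < len(_PATHWAY_THEMES) else f"PATHWAY_{i + 1:02d}"
        for i in range(config.n_pathways)
    ]
    with open(path, "w") as fh:
        for name in names:
            size = int(rng.integers(8, 16))
            idx = rng.choice(len(genes), size=size, replace=False)
            members = sorted(genes[int(j)].name for j in idx)
            fh.write(name + "\t" + name.replace("_", " ").title() + "\t" + "\t".join(members) + "\n")
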