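"""Readers and writers for the formats the pipeline touches.

Germline calls come in as per-sample VCF 4.x; functional/clinical/population
metadata as a tab-delimited annotation table keyed by (chrom, pos, ref, alt);
gene roles (tumor suppressor vs oncogene) as a two-column table; pathways as
GMT; and the cohort manifest — patients, germline sample, tumors, purities,
ethnicity labels — as YAML.

Conventions
-----------
* Coordinates are 1-based, fully closed (VCF convention), end to end.
* Multiallelic VCF records are decomposed: one :class:`VariantCall` per alt
  allele, with depth taken as the sum of the AD field.
* Genotypes 0/0 and ./. are dropped at read time — only carried alternative
  alleles matter for germline analysis.
* A missing population allele frequency is stored as 0.0: a variant absent
  from the population database is treated as novel (rare by definition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam
import yaml

from .errors import InputError, ParseError

# Effect classes on the protein product; "truncating" means stop_gained or
# frameshift throughout the package.
EFFECTS = frozenset(
    {"stop_gained", "frameshift", "synonymous", "missense", "splice", "other"}
)
TRUNCATING = frozenset({"stop_gained", "frameshift"})
CLINVAR_CLASSES = frozenset(
    {"pathogenic", "likely_pathogenic", "benign", "likely_benign", "vus", "absent"}
)

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantCall:
    """One alt-allele observation in one sample."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_quality: float
    depth: int
    alt_depth: int
    genotype: str  # het | hom_alt | hom_ref | missing
    vaf: float

    def __post_init__(self) -> None:
        if self.alt_depth > self.depth:
            raise InputError(
                f"alt_depth {self.alt_depth} > depth {self.depth} at "
                f"{self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def make_call(
    sample_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    site_quality: float,
    depth: int,
    alt_depth: int,
    genotype: str,
) -> VariantCall:
    """Construct a call with the VAF derived from the allele depths."""
    vaf = alt_depth / depth if depth > 0 else 0.0
    return VariantCall(
        sample_id, chrom, pos, ref, alt, site_quality, depth, alt_depth, genotype, vaf
    )


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional, clinical and population metadata for one (locus, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    canonical_effect: Optional[str]
    clinvar_class: str
    clinvar_condition_is_cancer: Optional[bool]  # None = unknown
    pop_af: float
    inbreeding_pass: bool
    vqsr_pass: bool
    cadd_phred: Optional[float]
    dbsnp: bool
    cosmic: bool

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def effective_effect(self) -> str:
        """Effect on the canonical transcript (longest CDS) when annotated."""
        return self.canonical_effect if self.canonical_effect else self.effect


def absent_annotation(chrom: str, pos: int, ref: str, alt: str) -> VariantAnnotation:
    """Sentinel for a variant not present in the annotation table."""
    return VariantAnnotation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene="",
        effect="other",
        canonical_effect=None,
        clinvar_class="absent",
        clinvar_condition_is_cancer=None,
        pop_af=0.0,
        inbreeding_pass=True,
        vqsr_pass=True,
        cadd_phred=None,
        dbsnp=False,
        cosmic=False,
    )


class AnnotationStore:
    """Lookup of :class:`VariantAnnotation` by (chrom, pos, ref, alt).

    Unknown keys resolve to the absent-annotation sentinel rather than an
    error, so downstream filters see "ClinVar absent, novel, QC pass".
    """

    def __init__(self, annotations: Iterable[VariantAnnotation] = ()) -> None:
        self._by_key: dict[VariantKey, VariantAnnotation] = {}
        for ann in annotations:
            self.add(ann)

    def add(self, ann: VariantAnnotation) -> None:
        if ann.key in self._by_key:
            raise InputError(f"duplicate annotation key {ann.key}")
        self._by_key[ann.key] = ann

    def get(self, key: VariantKey) -> VariantAnnotation:
        try:
            return self._by_key[key]
        except KeyError:
            return absent_annotation(*key)

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._by_key

    def genes(self) -> set[str]:
        """All gene symbols in the table (the default ORA universe)."""
        return {a.gene for a in self._by_key.values() if a.gene}

    def values(self) -> Iterable[VariantAnnotation]:
        return self._by_key.values()


class GeneRoleTable:
    """gene symbol -> role in {TSG, oncogene}; dual annotations resolve to TSG."""

    def __init__(self, roles: dict[str, str] | None = None) -> None:
        self._roles: dict[str, str] = dict(roles or {})

    def set_role(self, gene: str, role: str) -> None:
        if role not in ("TSG", "oncogene"):
            raise InputError(f"unknown gene role {role!r} for {gene}")
        # A gene annotated as both TSG and oncogene is treated as a TSG.
        if self._roles.get(gene) == "TSG":
            return
        self._roles[gene] = role

    def role(self, gene: str) -> Optional[str]:
        return self._roles.get(gene)

    def is_tsg(self, gene: str) -> bool:
        return self._roles.get(gene) == "TSG"

    def is_oncogene(self, gene: str) -> bool:
        return self._roles.get(gene) == "oncogene"

    def __len__(self) -> int:
        return len(self._roles)

    def genes(self) -> set[str]:
        return set(self._roles)


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    genes: frozenset[str]


class PathwayCollection:
    def __init__(self, pathways: Iterable[Pathway] = ()) -> None:
        self._by_id: dict[str, Pathway] = {}
        for pw in pathways:
            self.add(pw)

    def add(self, pathway: Pathway) -> None:
        if not pathway.genes:
            raise InputError(f"pathway {pathway.pathway_id} has no genes")
        if pathway.pathway_id in self._by_id:
            raise InputError(f"duplicate pathway id {pathway.pathway_id}")
        self._by_id[pathway.pathway_id] = pathway

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for pw in self:
            out |= pw.genes
        return out


@dataclass
class TumorSample:
    tumor_id: str
    site: str  # primary | metastatic
    purity: Optional[float] = None  # missing -> excluded from LOH by QC


@dataclass
class Patient:
    patient_id: str
    ethnicity: str
    germline_sample: str
    tumors: list[TumorSample] = field(default_factory=list)


@dataclass
class CohortManifest:
    patients: list[Patient]
    filter_profile: str = "wcm"

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def tumor_to_patient(self) -> dict[str, str]:
        return {t.tumor_id: p.patient_id for p in self.patients for t in p.tumors}

    def tumor(self, tumor_id: str) -> TumorSample:
        for p in self.patients:
            for t in p.tumors:
                if t.tumor_id == tumor_id:
                    return t
        raise InputError(f"tumor {tumor_id} not in manifest")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _genotype_for_alt(gt: tuple, allele_index: int) -> str:
    if gt is None or any(a is None for a in gt):
        return "missing"
    n_alt = sum(1 for a in gt if a == allele_index)
    if n_alt == 0:
        return "hom_ref"
    if n_alt == len(gt):
        return "hom_alt"
    return "het"


def read_vcf(path: str | Path, sample_id: str) -> list[VariantCall]:
    """Read a single-sample germline VCF into decomposed :class:`VariantCall`.

    Multiallelic rows are split into one call per alt allele; depth is the sum
    of the AD field (falling back to DP+AO when AD is absent). Genotypes 0/0
    and ./. are dropped. Output is sorted by (chrom, pos).
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed VCF header ({exc})") from exc
    calls: list[VariantCall] = []
    with vcf:
        n_header = sum(1 for _ in str(vcf.header).rstrip("\n").split("\n"))
        for i, rec in enumerate(vcf):
            line_no = n_header + i + 1
            if not rec.samples:
                raise ParseError(f"{path} line {line_no}: record has no sample data")
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or len(gt) == 0:
                raise ParseError(f"{path} line {line_no}: missing GT field")
            alts = rec.alts or ()
            if any(a is None for a in gt) or all(a == 0 for a in gt):
                continue  # missing or hom-ref genotype: dropped at read time
            ad = sample.get("AD")
            if ad is not None and not all(a is None for a in ad):
                depths = [a or 0 for a in ad]
                depth = int(sum(depths))
                alt_depths = {j + 1: int(depths[j + 1]) for j in range(len(alts))}
            else:
                dp = sample.get("DP")
                ao = sample.get("AO")
                if dp is None or ao is None:
                    raise ParseError(
                        f"{path} line {line_no}: no AD and no DP+AO depth fields"
                    )
                if isinstance(ao, int):
                    ao = (ao,)
                depth = int(dp)
                alt_depths = {j + 1: int(ao[j]) for j in range(len(alts))}
            qual = float(rec.qual) if rec.qual is not None else 0.0
            for j, alt in enumerate(alts, start=1):
                genotype = _genotype_for_alt(gt, j)
                if genotype in ("hom_ref", "missing"):
                    continue
                calls.append(
                    make_call(
                        sample_id,
                        rec.chrom,
                        rec.pos,
                        rec.ref,
                        str(alt),
                        qual,
                        depth,
                        alt_depths[j],
                        genotype,
                    )
                )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def vcf_contig_lines(calls: Iterable) -> str:
    chroms = sorted({c.chrom for c in calls})
    return "".join(f"##contig=<ID={ch}>\n" for ch in chroms)


def write_vcf(calls: Iterable[VariantCall], path: str | Path, sample_id: str) -> None:
    """Write decomposed calls back to a single-sample VCF (one row per call)."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    gt_map = {"het": "0/1", "hom_alt": "1/1", "hom_ref": "0/0", "missing": "./."}
    with open(path, "w") as fh:
        fh.write(
            _VCF_HEADER.format(sample=sample_id, contigs=vcf_contig_lines(calls))
        )
        for c in calls:
            ad = f"{c.depth - c.alt_depth},{c.alt_depth}"
            qual = f"{c.site_quality:g}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{qual}\t.\t.\t"
                f"GT:AD\t{gt_map[c.genotype]}:{ad}\n"
            )


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

_ANN_REQUIRED = [
    "chrom", "pos", "ref", "alt", "gene", "effect", "clinvar_class", "pop_af",
    "inbreeding_pass", "vqsr_pass",
]


def _parse_bool(value, default: Optional[bool] = None) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    if s in ("", "unknown", "na", "nan", "."):
        return default
    raise InputError(f"cannot parse boolean value {value!r}")


def read_annotation_table(path: str | Path) -> AnnotationStore:
    """Load the tab-delimited per-variant annotation table.

    Required columns: chrom, pos, ref, alt, gene, effect, clinvar_class,
    pop_af, inbreeding_pass, vqsr_pass. Optional: canonical_effect,
    clinvar_condition_is_cancer, cadd_phred, dbsnp, cosmic.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _ANN_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    store = AnnotationStore()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        effect = str(row.effect)
        if effect not in EFFECTS:
            raise ParseError(f"{path} line {idx}: unknown effect {effect!r}")
        canonical = getattr(row, "canonical_effect", None)
        if canonical is not None and (
            not isinstance(canonical, str) or canonical in ("", ".")
        ):
            canonical = None
        if canonical is not None and canonical not in EFFECTS:
            raise ParseError(f"{path} line {idx}: unknown canonical effect {canonical!r}")
        clinvar = str(row.clinvar_class)
        if clinvar not in CLINVAR_CLASSES:
            raise ParseError(f"{path} line {idx}: unknown ClinVar class {clinvar!r}")
        pop_af = row.pop_af
        if pop_af is None or (isinstance(pop_af, float) and math.isnan(pop_af)):
            pop_af = 0.0  # absent from the population database -> novel
        pop_af = float(pop_af)
        if not 0.0 <= pop_af <= 1.0:
            raise ParseError(f"{path} line {idx}: pop_af {pop_af} outside [0, 1]")
        cadd = getattr(row, "cadd_phred", None)
        if cadd is not None and isinstance(cadd, float) and math.isnan(cadd):
            cadd = None
        if cadd is not None:
            cadd = float(cadd)
            if cadd < 0:
                raise ParseError(f"{path} line {idx}: negative CADD score {cadd}")
        ann = VariantAnnotation(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            gene=str(row.gene),
            effect=effect,
            canonical_effect=canonical,
            clinvar_class=clinvar,
            clinvar_condition_is_cancer=_parse_bool(
                getattr(row, "clinvar_condition_is_cancer", None)
            ),
            pop_af=pop_af,
            inbreeding_pass=bool(_parse_bool(row.inbreeding_pass, default=True)),
            vqsr_pass=bool(_parse_bool(row.vqsr_pass, default=True)),
            cadd_phred=cadd,
            dbsnp=bool(_parse_bool(getattr(row, "dbsnp", None), default=False)),
            cosmic=bool(_parse_bool(getattr(row, "cosmic", None), default=False)),
        )
        try:
            store.add(ann)
        except InputError as exc:
            raise ParseError(f"{path} line {idx}: {exc}") from exc
    return store


def read_gene_roles(path: str | Path) -> GeneRoleTable:
    """Two-column TSV (gene, role); duplicate genes with both roles become TSG."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "role" not in df.columns:
        raise ParseError(f"{path}: gene role table needs 'gene' and 'role' columns")
    table = GeneRoleTable()
    for row in df.itertuples(index=False):
        table.set_role(str(row.gene), str(row.role))
    return table


def read_gene_sets(path: str | Path) -> PathwayCollection:
    """Standard GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    collection = PathwayCollection()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path} line {line_no}: GMT line with <1 gene")
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path} line {line_no}: GMT line with <1 gene")
            collection.add(Pathway(pathway_id=name, name=desc or name, genes=genes))
    return collection


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> CohortManifest:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "patients" not in raw:
        raise ParseError(f"{path}: manifest must contain a 'patients' list")
    patients = []
    for p in raw["patients"]:
        tumors = []
        for t in p.get("tumors", []):
            site = t.get("site", "primary")
            if site not in ("primary", "metastatic"):
                raise ParseError(f"{path}: bad tumor site {site!r}")
            purity = t.get("purity")
            if purity is not None:
                purity = float(purity)
                if not 0.0 < purity <= 1.0:
                    raise ParseError(f"{path}: purity {purity} outside (0, 1]")
            tumors.append(TumorSample(str(t["tumor_id"]), site, purity))
        patients.append(
            Patient(
                patient_id=str(p["patient_id"]),
                ethnicity=str(p.get("ethnicity", "unknown")),
                germline_sample=str(p.get("germline_sample", p["patient_id"])),
                tumors=tumors,
            )
        )
    return CohortManifest(patients=patients, filter_profile=raw.get("filter_profile", "wcm"))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    raw = {
        "filter_profile": manifest.filter_profile,
        "patients": [
            {
                "patient_id": p.patient_id,
                "ethnicity": p.ethnicity,
                "germline_sample": p.germline_sample,
                "tumors": [
                    {
                        "tumor_id": t.tumor_id,
                        "site": t.site,
                        **({"purity": round(float(t.purity), 4)} if t.purity is not None else {}),
                    }
                    for t in p.tumors
                ],
            }
            for p in manifest.patients
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def read_exclusion_list(path: str | Path) -> set[VariantKey]:
    """Variant keys excluded by manual review (chrom, pos, ref, alt TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise ParseError(f"{path}: exclusion list needs column {col!r}")
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples(index=False)
    }
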