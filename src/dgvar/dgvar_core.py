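"""The DGVar filter cascade.

Reduces raw germline calls to putative deleterious germline variants (pDGVs):
variants classified pathogenic/likely-pathogenic in ClinVar (for a cancer or
unknown condition), or protein-truncating (stop gain / frameshift) in a tumor
suppressor gene, that survive a series of QC filters. Every variant carries a
full per-filter trace, and removals are attributed to the first failing filter
so that input = output + sum(per-reason removals) holds exactly.

Boundary semantics: the removal conditions are "quality lower than 50",
"coverage < 10x", "VAF less than 35%", "> 1% population AF", "> 5% cohort
recurrence" — the retained region is the exact complement, so values at the
boundary (quality 50, depth 10, VAF 0.35, AF 0.01, recurrence 0.05) are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

from .errors import InputError
from .io_cohort import (
    AnnotationStore,
    GeneRoleTable,
    VariantCall,
    VariantKey,
    TRUNCATING,
)

# Filter names, in cascade order. Removals are attributed to the first
# failing entry of this list.
FILTER_ORDER = (
    "site_quality",
    "depth",
    "vaf",
    "snv_cluster",
    "pop_af",
    "classification",
    "cohort_recurrence",
    "exclusion_list",
)


@dataclass(frozen=True)
class FilterProfile:
    """Cohort-specific QC thresholds.

    ``snv_cluster_min_count=None`` disables the SNV-cluster rule (used for
    cohorts called with DeepVariant-style pipelines where the rule was not
    applied).
    """

    name: str
    min_site_quality: float
    min_depth: int
    min_vaf: float
    max_pop_af: float = 0.01
    cohort_recurrence_max: float = 0.05
    snv_cluster_window: int = 10
    snv_cluster_min_count: Optional[int] = 3
    require_exac_qc: bool = True
    restrict_to_tsg: bool = False

    def __post_init__(self) -> None:
        if self.snv_cluster_window < 1:
            raise InputError("snv_cluster_window must be >= 1")


#: Shipped profiles. "wcm" mirrors the exome cohort QC (quality >= 50, depth
#: >= 10x, VAF >= 35%, 3-SNVs-in-10bp cluster rule); "spark" mirrors the
#: non-cancer comparison cohort QC (quality >= 30, depth >= 8, VAF >= 20%, no
#: cluster rule).
PROFILES: dict[str, FilterProfile] = {
    "wcm": FilterProfile("wcm", 50.0, 10, 0.35),
    "spark": FilterProfile(
        "spark", 30.0, 8, 0.20, snv_cluster_min_count=None
    ),
}


@dataclass(frozen=True)
class PDGVRecord:
    """A variant that survived the cascade, with its qualifying reason."""

    patient_id: str
    call: VariantCall
    gene: str
    role: Optional[str]
    reason: str  # clinvar_pathogenic | tsg_truncating | both
    filter_trace: tuple[tuple[str, bool], ...]

    @property
    def key(self) -> VariantKey:
        return self.call.key


@dataclass
class CascadeResult:
    """Retained records plus a per-reason removal accounting."""

    records: list[PDGVRecord]
    removed: list[tuple[str, VariantCall, str]]  # (patient, call, first failing filter)
    removal_counts: dict[str, int]
    n_input: int

    @property
    def n_retained(self) -> int:
        return len(self.records)

    def conserved(self) -> bool:
        """input = output + sum of per-reason removals."""
        return self.n_input == self.n_retained + sum(self.removal_counts.values())


def apply_quality_filters(
    calls: Iterable[VariantCall], profile: FilterProfile
) -> tuple[list[VariantCall], list[tuple[VariantCall, list[tuple[str, bool]]]]]:
    """Site-quality / depth / VAF filter; returns (retained, full trace).

    The VAF floor removes sub-heterozygous calls that may reflect clonal
    hematopoiesis (CHIP) rather than true germline variation.
    """
    retained = []
    trace = []
    for call in calls:
        entries = [
            ("site_quality", call.site_quality >= profile.min_site_quality),
            ("depth", call.depth >= profile.min_depth),
            ("vaf", call.vaf >= profile.min_vaf),
        ]
        trace.append((call, entries))
        if all(ok for _, ok in entries):
            retained.append(call)
    return retained, trace


def flag_alignment_clusters(
    calls: Iterable[VariantCall], window: int = 10, min_count: int = 3
) -> set[VariantCall]:
    """Flag SNVs in dense clusters suggestive of alignment artifacts.

    An SNV is flagged iff some interval of span <= ``window`` bp on the same
    chromosome contains >= ``min_count`` SNVs of the sample. Indels are never
    flagged. Calls must come from a single sample.
    """
    snvs = [c for c in calls if c.is_snv]
    flagged: set[VariantCall] = set()
    by_chrom: dict[str, list[VariantCall]] = {}
    for c in snvs:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom_calls in by_chrom.values():
        chrom_calls.sort(key=lambda c: c.pos)
        n = len(chrom_calls)
        j = 0
        for i in range(n):
            # widest window starting at call i: positions p .. p + window - 1
            if j < i:
                j = i
            while j + 1 < n and chrom_calls[j + 1].pos <= chrom_calls[i].pos + window - 1:
                j += 1
            if j - i + 1 >= min_count:
                flagged.update(chrom_calls[i : j + 1])
    return flagged


def classify_variant(
    call: VariantCall,
    annotation,
    roles: GeneRoleTable,
    require_exac_qc: bool = True,
    restrict_to_tsg: bool = False,
) -> str:
    """Classify one variant for pDGV purposes.

    Returns one of clinvar_pathogenic | tsg_truncating | both |
    clinvar_benign | neutral. ClinVar pathogenic/likely-pathogenic variants
    reported for a non-cancer condition are excluded (classified neutral);
    condition unknown counts as potentially cancer-related. TSG truncations
    must pass the population-database inbreeding-coefficient and VQSR filters
    when ``require_exac_qc`` is set.
    """
    if annotation.clinvar_class in ("benign", "likely_benign"):
        return "clinvar_benign"
    clinvar_hit = (
        annotation.clinvar_class in ("pathogenic", "likely_pathogenic")
        and annotation.clinvar_condition_is_cancer in (True, None)
        and (not restrict_to_tsg or roles.is_tsg(annotation.gene))
    )
    exac_ok = (not require_exac_qc) or (
        annotation.inbreeding_pass and annotation.vqsr_pass
    )
    tsg_hit = (
        annotation.effective_effect in TRUNCATING
        and roles.is_tsg(annotation.gene)
        and exac_ok
    )
    if clinvar_hit and tsg_hit:
        return "both"
    if clinvar_hit:
        return "clinvar_pathogenic"
    if tsg_hit:
        return "tsg_truncating"
    return "neutral"


def _carrier_fractions(
    cohort: Mapping[str, Iterable[VariantCall]]
) -> dict[VariantKey, float]:
    """Fraction of cohort patients carrying each variant key."""
    n = len(cohort)
    if n == 0:
        raise InputError("cohort recurrence filter requires a non-empty cohort")
    carriers: dict[VariantKey, set[str]] = {}
    for patient_id, calls in cohort.items():
        for call in calls:
            carriers.setdefault(call.key, set()).add(patient_id)
    return {key: len(pats) / n for key, pats in carriers.items()}


def _evaluate_cascade(
    cohort: Mapping[str, list[VariantCall]],
    annotations: AnnotationStore,
    profile: FilterProfile,
    *,
    keep,
    exclusion_list: frozenset | set = frozenset(),
) -> tuple[list[tuple[str, VariantCall, tuple[tuple[str, bool], ...]]],
           list[tuple[str, VariantCall, str]], dict[str, int], int]:
    """Shared cascade walk.

    ``keep(call, annotation)`` decides the "classification" entry — pDGV
    classification for the main cascade, synonymous-and-rare for the rare
    synonymous extraction. Returns (retained with trace, removed, counts, n).
    """
    recurrence = _carrier_fractions(cohort)
    counts = {name: 0 for name in FILTER_ORDER}
    retained = []
    removed = []
    n_input = 0
    for patient_id in sorted(cohort):
        calls = cohort[patient_id]
        n_input += len(calls)
        if profile.snv_cluster_min_count is not None:
            clustered = flag_alignment_clusters(
                calls, profile.snv_cluster_window, profile.snv_cluster_min_count
            )
        else:
            clustered = set()
        for call in calls:
            ann = annotations.get(call.key)
            entries = (
                ("site_quality", call.site_quality >= profile.min_site_quality),
                ("depth", call.depth >= profile.min_depth),
                ("vaf", call.vaf >= profile.min_vaf),
                ("snv_cluster", call not in clustered),
                ("pop_af", ann.pop_af <= profile.max_pop_af),
                ("classification", keep(call, ann)),
                (
                    "cohort_recurrence",
                    recurrence[call.key] <= profile.cohort_recurrence_max,
                ),
                ("exclusion_list", call.key not in exclusion_list),
            )
            if all(ok for _, ok in entries):
                retained.append((patient_id, call, entries))
            else:
                first_fail = next(name for name, ok in entries if not ok)
                counts[first_fail] += 1
                removed.append((patient_id, call, first_fail))
    return retained, removed, counts, n_input


def call_pdgvs(
    cohort: Mapping[str, list[VariantCall]],
    annotations: AnnotationStore,
    roles: GeneRoleTable,
    profile: FilterProfile,
    exclusion_list: frozenset | set = frozenset(),
) -> CascadeResult:
    """Run the full cascade over a cohort and return pDGVs with traces.

    A call is a pDGV iff it passes the quality/depth/VAF filters, is not in
    an SNV alignment cluster, has population AF <= the rarity cap, classifies
    as ClinVar-pathogenic and/or TSG-truncating, is carried by no more than
    the recurrence cap of cohort patients (platform-artifact removal), and is
    not on the manual-review exclusion list.
    """

    def keep(call, ann):
        cls = classify_variant(
            call, ann, roles, profile.require_exac_qc, profile.restrict_to_tsg
        )
        return cls in ("clinvar_pathogenic", "tsg_truncating", "both")

    retained, removed, counts, n_input = _evaluate_cascade(
        cohort, annotations, profile, keep=keep, exclusion_list=exclusion_list
    )
    records = []
    for patient_id, call, entries in retained:
        ann = annotations.get(call.key)
        cls = classify_variant(
            call, ann, roles, profile.require_exac_qc, profile.restrict_to_tsg
        )
        records.append(
            PDGVRecord(
                patient_id=patient_id,
                call=call,
                gene=ann.gene,
                role=roles.role(ann.gene),
                reason=cls,
                filter_trace=entries,
            )
        )
    return CascadeResult(records, removed, counts, n_input)


def extract_rare_synonymous(
    cohort: Mapping[str, list[VariantCall]],
    annotations: AnnotationStore,
    profile: FilterProfile,
    max_pop_af: float = 0.01,
) -> CascadeResult:
    """Rare synonymous variants under the same QC as pDGVs.

    Retains calls whose canonical effect is synonymous with population AF
    strictly below ``max_pop_af`` (1% default), passing the same quality /
    VAF / cluster / population-QC / cohort-recurrence filters. These form the
    denominator of the burden enrichment test.
    """

    def keep(call, ann):
        exac_ok = (not profile.require_exac_qc) or (
            ann.inbreeding_pass and ann.vqsr_pass
        )
        return (
            ann.effective_effect == "synonymous"
            and ann.pop_af < max_pop_af
            and exac_ok
        )

    retained, removed, counts, n_input = _evaluate_cascade(
        cohort, annotations, profile, keep=keep
    )
    records = []
    for patient_id, call, entries in retained:
        ann = annotations.get(call.key)
        records.append(
            PDGVRecord(
                patient_id=patient_id,
                call=call,
                gene=ann.gene,
                role=None,
                reason="rare_synonymous",
                filter_trace=entries,
            )
        )
    return CascadeResult(records, removed, counts, n_input)


def tighten(profile: FilterProfile, **overrides) -> FilterProfile:
    """Convenience for building a modified profile (used in property tests)."""
    return replace(profile, **overrides)
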