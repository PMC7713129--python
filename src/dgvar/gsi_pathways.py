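"""Germline–somatic interactions (GSIs) at gene and pathway level.

A gene-level GSI is a pDGV coexisting with a qualifying somatic event in the
same tumor suppressor gene of the same patient's tumor — the two-hit pattern
in cis. Qualifying somatic events in a TSG are protein-truncating mutations
or copy-number losses; in an oncogene, non-truncating (and non-synonymous)
mutations.

Pathway-level GSIs extend the idea in trans: the union of a tumor's germline
pDGV genes and qualifying somatic genes is tested per pathway with an
upper-tail hypergeometric over-representation test (ORA), and a pathway is a
GSI when p < alpha (strict) AND it contains at least one germline-hit gene
and at least one somatic-hit gene. Pathways with identical gene sets (same
pathway from multiple source collections) are merged. No multiple-testing
correction is applied at the stated alpha by default; Benjamini–Hochberg is
available as an option.

The per-patient pathway enrichment score
``log10(1000 * k / (m * K) + 1)`` — k pathway genes with DGVs, m patient
genes with DGVs, K pathway size — ranks how unlikely a pathway is to be hit
by chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .errors import InputError
from .io_cohort import (
    AnnotationStore,
    GeneRoleTable,
    Pathway,
    PathwayCollection,
    TRUNCATING,
)
from .dgvar_core import PDGVRecord
from .somatic_consensus import CopyNumberEvent, SomaticCall


@dataclass(frozen=True)
class PathwayScoreInput:
    n_pathway_dgv_genes: int
    n_patient_dgv_genes: int
    n_pathway_genes: int

    def __post_init__(self) -> None:
        if min(self.n_pathway_dgv_genes, self.n_patient_dgv_genes, self.n_pathway_genes) < 0:
            raise InputError("pathway score inputs must be non-negative")
        if self.n_pathway_dgv_genes > min(self.n_patient_dgv_genes, self.n_pathway_genes):
            raise InputError("pathway DGV genes exceed patient DGV genes or pathway size")


@dataclass
class GeneGSI:
    patient_id: str
    tumor_id: str
    gene: str
    germline_key: tuple
    somatic_kind: str  # truncating_mutation | cn_loss


@dataclass
class PathwayGSI:
    patient_id: str
    tumor_id: str
    pathway_id: str
    germline_genes: frozenset[str]
    somatic_genes: frozenset[str]
    p_value: float
    private: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.germline_genes or not self.somatic_genes:
            raise InputError("a pathway GSI needs both germline and somatic genes")
        if not 0.0 <= self.p_value <= 1.0:
            raise InputError("p-value outside [0, 1]")


def enrichment_score(score_input: PathwayScoreInput) -> float:
    """log10(1000 * k / (m * K) + 1); 0 when the pathway has no DGV gene."""
    m, K = score_input.n_patient_dgv_genes, score_input.n_pathway_genes
    if m == 0 or K == 0:
        raise InputError("enrichment score denominator is zero")
    return math.log10(1000.0 * score_input.n_pathway_dgv_genes / (m * K) + 1.0)


def ora_test(
    query_genes: set[str], pathway_genes: set[str] | frozenset[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric over-representation p-value.

    P(X >= overlap) with population size |universe|, |pathway| successes and
    |query| draws. Query and pathway must be subsets of the universe.
    """
    if not universe:
        raise InputError("empty gene universe")
    if not set(query_genes) <= set(universe):
        raise InputError("query genes outside the universe")
    if not set(pathway_genes) <= set(universe):
        raise InputError("pathway genes outside the universe")
    overlap = len(set(query_genes) & set(pathway_genes))
    return float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(pathway_genes), len(query_genes))
    )


def qualifying_somatic_genes(
    somatic_calls: Iterable[SomaticCall],
    cn_events: Iterable[CopyNumberEvent],
    annotations: AnnotationStore,
    roles: GeneRoleTable,
) -> set[str]:
    """Genes with role-consistent somatic hits in one tumor.

    TSGs qualify through truncating mutations or copy-number losses;
    oncogenes through non-truncating, non-synonymous mutations. Genes with
    no role annotation do not qualify.
    """
    genes: set[str] = set()
    for call in somatic_calls:
        ann = annotations.get(call.key)
        if not ann.gene:
            continue
        effect = ann.effective_effect
        if roles.is_tsg(ann.gene) and effect in TRUNCATING:
            genes.add(ann.gene)
        elif roles.is_oncogene(ann.gene) and effect not in TRUNCATING and effect != "synonymous":
            genes.add(ann.gene)
    for ev in cn_events:
        if ev.direction == "loss" and roles.is_tsg(ev.gene):
            genes.add(ev.gene)
    return genes


def gene_level_gsi(
    pdgvs: Sequence[PDGVRecord],
    somatic_by_tumor: Mapping[str, Sequence[SomaticCall]],
    cn_by_tumor: Mapping[str, Sequence[CopyNumberEvent]],
    annotations: AnnotationStore,
    roles: GeneRoleTable,
    tumor_to_patient: Mapping[str, str],
) -> list[GeneGSI]:
    """Two-hit (cis) events: a pDGV plus a somatic hit in the same TSG."""
    pdgv_genes_by_patient: dict[str, dict[str, PDGVRecord]] = {}
    for rec in pdgvs:
        if rec.gene:
            pdgv_genes_by_patient.setdefault(rec.patient_id, {})[rec.gene] = rec
    out: list[GeneGSI] = []
    tumors = sorted(set(somatic_by_tumor) | set(cn_by_tumor))
    for tumor_id in tumors:
        patient_id = tumor_to_patient.get(tumor_id)
        if patient_id is None or patient_id not in pdgv_genes_by_patient:
            continue
        patient_pdgvs = pdgv_genes_by_patient[patient_id]
        hit: dict[str, str] = {}
        for call in somatic_by_tumor.get(tumor_id, ()):
            ann = annotations.get(call.key)
            if (
                ann.gene in patient_pdgvs
                and roles.is_tsg(ann.gene)
                and ann.effective_effect in TRUNCATING
            ):
                hit.setdefault(ann.gene, "truncating_mutation")
        for ev in cn_by_tumor.get(tumor_id, ()):
            if ev.direction == "loss" and ev.gene in patient_pdgvs and roles.is_tsg(ev.gene):
                hit.setdefault(ev.gene, "cn_loss")
        for gene in sorted(hit):
            out.append(
                GeneGSI(
                    patient_id=patient_id,
                    tumor_id=tumor_id,
                    gene=gene,
                    germline_key=patient_pdgvs[gene].key,
                    somatic_kind=hit[gene],
                )
            )
    return out


def merge_identical_pathways(pathways: PathwayCollection) -> list[Pathway]:
    """Merge pathways with identical gene sets (multi-source duplicates)."""
    by_genes: dict[frozenset[str], list[Pathway]] = {}
    for pw in pathways:
        by_genes.setdefault(pw.genes, []).append(pw)
    merged = []
    for genes, group in by_genes.items():
        group.sort(key=lambda p: p.pathway_id)
        if len(group) == 1:
            merged.append(group[0])
        else:
            merged.append(
                Pathway(
                    pathway_id="|".join(p.pathway_id for p in group),
                    name=group[0].name,
                    genes=genes,
                )
            )
    merged.sort(key=lambda p: p.pathway_id)
    return merged


def _bh_adjust(pvalues: list[float]) -> list[float]:
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = n - rank_from_end
        running = min(running, pvalues[idx] * n / rank)
        adjusted[idx] = running
    return adjusted


def pathway_level_gsi(
    pdgvs: Sequence[PDGVRecord],
    somatic_by_tumor: Mapping[str, Sequence[SomaticCall]],
    cn_by_tumor: Mapping[str, Sequence[CopyNumberEvent]],
    pathways: PathwayCollection,
    annotations: AnnotationStore,
    roles: GeneRoleTable,
    tumor_to_patient: Mapping[str, str],
    universe: Optional[set[str]] = None,
    alpha: float = 0.05,
    allowlist: Optional[set[str]] = None,
    bh_correct: bool = False,
) -> list[PathwayGSI]:
    """Per-tumor pathway GSIs via hypergeometric ORA.

    For each tumor, the query is the union of the patient's germline pDGV
    genes and the tumor's role-qualified somatic genes. A pathway is emitted
    when its ORA p (optionally BH-adjusted across pathways within the tumor)
    is strictly below ``alpha`` and it harbors both germline and somatic
    genes. ``allowlist`` restricts the tested pathways (the cancer-associated
    pathway curation); default tests all. ``universe`` defaults to all genes
    in the annotation table. ``private`` is filled per patient: a GSI is
    private when its pathway appears in no other tumor of the same patient.
    """
    if universe is None:
        universe = annotations.genes()
    universe = set(universe) | {r.gene for r in pdgvs if r.gene}
    merged = merge_identical_pathways(pathways)
    if allowlist is not None:
        allowed = set()
        for pw in merged:
            parts = set(pw.pathway_id.split("|"))
            if parts & allowlist:
                allowed.add(pw.pathway_id)
        merged = [pw for pw in merged if pw.pathway_id in allowed]
    universe |= {g for pw in merged for g in pw.genes}

    germline_by_patient: dict[str, set[str]] = {}
    for rec in pdgvs:
        if rec.gene:
            germline_by_patient.setdefault(rec.patient_id, set()).add(rec.gene)

    gsis: list[PathwayGSI] = []
    tumors = sorted(set(somatic_by_tumor) | set(cn_by_tumor))
    for tumor_id in tumors:
        patient_id = tumor_to_patient.get(tumor_id)
        if patient_id is None:
            continue
        germline_genes = germline_by_patient.get(patient_id, set())
        somatic_genes = qualifying_somatic_genes(
            somatic_by_tumor.get(tumor_id, ()),
            cn_by_tumor.get(tumor_id, ()),
            annotations,
            roles,
        )
        if not germline_genes or not somatic_genes:
            continue
        query = germline_genes | somatic_genes
        pvals = [ora_test(query, pw.genes, universe) for pw in merged]
        if bh_correct:
            pvals = _bh_adjust(pvals)
        for pw, p in zip(merged, pvals):
            g_hits = frozenset(pw.genes & germline_genes)
            s_hits = frozenset(pw.genes & somatic_genes)
            if p < alpha and g_hits and s_hits:
                gsis.append(
                    PathwayGSI(
                        patient_id=patient_id,
                        tumor_id=tumor_id,
                        pathway_id=pw.pathway_id,
                        germline_genes=g_hits,
                        somatic_genes=s_hits,
                        p_value=float(p),
                    )
                )
    _fill_private_flags(gsis)
    return gsis


def _fill_private_flags(gsis: list[PathwayGSI]) -> None:
    by_patient: dict[str, dict[str, set[str]]] = {}
    for g in gsis:
        by_patient.setdefault(g.patient_id, {}).setdefault(g.tumor_id, set()).add(
            g.pathway_id
        )
    for g in gsis:
        others: set[str] = set()
        for tumor_id, pws in by_patient[g.patient_id].items():
            if tumor_id != g.tumor_id:
                others |= pws
        g.private = g.pathway_id not in others


def private_gsi_fraction(
    gsis: Sequence[PathwayGSI],
    tumors_by_patient: Optional[Mapping[str, Sequence[str]]] = None,
) -> float:
    """Fraction of tumors with at least one private pathway GSI.

    The denominator is the set of tumors belonging to patients with >= 2
    tumors (single-tumor patients cannot have shared vs private pathways).
    ``tumors_by_patient`` supplies the full tumor census; when omitted it is
    derived from the GSIs themselves (tumors with no GSI then drop out).
    """
    if tumors_by_patient is None:
        derived: dict[str, set[str]] = {}
        for g in gsis:
            derived.setdefault(g.patient_id, set()).add(g.tumor_id)
        tumors_by_patient = {p: sorted(ts) for p, ts in derived.items()}
    multi = {
        p: list(ts) for p, ts in tumors_by_patient.items() if len(set(ts)) >= 2
    }
    if not multi:
        raise InputError("no patient with >= 2 tumors")
    pathways_by_tumor: dict[tuple[str, str], set[str]] = {}
    for g in gsis:
        pathways_by_tumor.setdefault((g.patient_id, g.tumor_id), set()).add(g.pathway_id)
    n_tumors = 0
    n_private = 0
    for patient_id, tumors in multi.items():
        for tumor_id in set(tumors):
            n_tumors += 1
            own = pathways_by_tumor.get((patient_id, tumor_id), set())
            others: set[str] = set()
            for other in set(tumors) - {tumor_id}:
                others |= pathways_by_tumor.get((patient_id, other), set())
            if own - others:
                n_private += 1
    return n_private / n_tumors
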