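"""End-to-end orchestration over a cohort bundle.

``run_all`` loads a bundle (manifest, germline VCFs, annotation table, gene
roles, pathways, tumor observations, caller VCFs, copy-number events), runs
every stage in dependency order — pDGV calling, rare synonymous extraction,
CADD comparison, LOH, somatic consensus, gene- and pathway-level GSIs — and
writes one TSV per stage plus a JSON run report whose per-filter removal
counts reconcile exactly with input and output sizes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import InputError
from .io_cohort import (
    CohortManifest,
    read_annotation_table,
    read_exclusion_list,
    read_gene_roles,
    read_gene_sets,
    read_manifest,
    read_vcf,
)
from .dgvar_core import PROFILES, CascadeResult, call_pdgvs, extract_rare_synonymous
from .enrichment_stats import cadd_scores, compare_cadd, sample_truncating_background
from .loh_analysis import (
    TumorObservation,
    annotate_loh,
    build_background_controls,
    compare_paired_primary_met,
    compare_vaf_densities,
    corrected_vaf,
    loh_fraction,
)
from .somatic_consensus import (
    CALLERS,
    apply_somatic_filters,
    merge_callers,
    read_caller_vcf,
    read_cn_events,
)
from .gsi_pathways import (
    gene_level_gsi,
    pathway_level_gsi,
    private_gsi_fraction,
)


@dataclass
class RunReport:
    seed: int
    version: str
    config_digest: str
    n_patients: int
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "version": self.version,
            "config_digest": self.config_digest,
            "n_patients": self.n_patients,
            "stages": self.stages,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def conserved(self) -> bool:
        """Every stage: input = output + sum of per-reason removals."""
        for stage in self.stages.values():
            if {"n_input", "n_output", "removed"} <= set(stage):
                if stage["n_input"] != stage["n_output"] + sum(stage["removed"].values()):
                    return False
        return True


def _stage_entry(result: CascadeResult) -> dict:
    return {
        "n_input": result.n_input,
        "n_output": result.n_retained,
        "removed": dict(result.removal_counts),
    }


def _pdgv_frame(result: CascadeResult) -> pd.DataFrame:
    rows = []
    for r in result.records:
        rows.append({
            "patient_id": r.patient_id,
            "chrom": r.call.chrom,
            "pos": r.call.pos,
            "ref": r.call.ref,
            "alt": r.call.alt,
            "gene": r.gene,
            "role": r.role or "",
            "reason": r.reason,
            "genotype": r.call.genotype,
            "vaf": round(r.call.vaf, 4),
            "depth": r.call.depth,
            "site_quality": r.call.site_quality,
            "filter_trace": ";".join(f"{n}={'pass' if ok else 'fail'}" for n, ok in r.filter_trace),
        })
    return pd.DataFrame(rows, columns=[
        "patient_id", "chrom", "pos", "ref", "alt", "gene", "role", "reason",
        "genotype", "vaf", "depth", "site_quality", "filter_trace",
    ])


def read_tumor_observations(path: str | Path, manifest: CohortManifest) -> list[TumorObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    t2p = manifest.tumor_to_patient()
    obs = []
    for row in df.itertuples(index=False):
        tumor_id = str(row.tumor_id)
        if tumor_id not in t2p:
            raise InputError(f"tumor {tumor_id} in observations but not in manifest")
        tumor = manifest.tumor(tumor_id)
        obs.append(TumorObservation(
            tumor_id=tumor_id,
            patient_id=t2p[tumor_id],
            site=tumor.site,
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            ref_reads=int(row.ref_reads),
            alt_reads=int(row.alt_reads),
            purity=tumor.purity,
        ))
    return obs


def run_all(
    bundle_dir: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    profile_name: Optional[str] = None,
    loh_threshold: float = 1.6,
    alpha: float = 0.05,
) -> RunReport:
    """Run every stage over an on-disk bundle; write stage TSVs and a report."""
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = read_manifest(bundle / "manifest.yaml")
    annotations = read_annotation_table(bundle / "annotations.tsv")
    roles = read_gene_roles(bundle / "gene_roles.tsv")
    pathways = read_gene_sets(bundle / "pathways.gmt")
    exclusion_path = bundle / "exclusion_list.tsv"
    exclusion = read_exclusion_list(exclusion_path) if exclusion_path.exists() else set()

    profile = PROFILES[profile_name or manifest.filter_profile]

    cohort = {}
    for patient in manifest.patients:
        vcf_path = bundle / "germline" / f"{patient.patient_id}.vcf"
        if not vcf_path.exists():
            raise InputError(f"missing germline VCF {vcf_path}")
        cohort[patient.patient_id] = read_vcf(vcf_path, patient.patient_id)

    config_digest = hashlib.sha256(json.dumps({
        "profile": profile.name,
        "loh_threshold": loh_threshold,
        "alpha": alpha,
        "seed": seed,
        "patients": sorted(cohort),
    }, sort_keys=True).encode()).hexdigest()[:16]

    report = RunReport(
        seed=seed,
        version=__version__,
        config_digest=config_digest,
        n_patients=len(cohort),
    )

    # --- pDGV cascade -------------------------------------------------------
    pdgv_result = call_pdgvs(cohort, annotations, roles, profile, frozenset(exclusion))
    _pdgv_frame(pdgv_result).to_csv(out / "pdgv.tsv", sep="\t", index=False)
    per_patient = {p: 0 for p in cohort}
    for r in pdgv_result.records:
        per_patient[r.patient_id] += 1
    report.stages["pdgv"] = {
        **_stage_entry(pdgv_result),
        "median_per_patient": float(np.median(list(per_patient.values()))),
        "patients_with_pdgv": sum(1 for v in per_patient.values() if v > 0),
    }

    syn_result = extract_rare_synonymous(cohort, annotations, profile)
    _pdgv_frame(syn_result).to_csv(out / "rare_synonymous.tsv", sep="\t", index=False)
    report.stages["rare_synonymous"] = _stage_entry(syn_result)

    # --- CADD comparison ----------------------------------------------------
    background = sample_truncating_background(
        cohort, annotations, roles, n_per_patient=20, rng=seed
    )
    pdgv_cadd = cadd_scores([r.call for r in pdgv_result.records], annotations)
    bg_cadd = cadd_scores(background, annotations)
    cadd_p = compare_cadd(pdgv_cadd, bg_cadd) if pdgv_cadd and bg_cadd else None
    report.stages["cadd"] = {
        "n_pdgv_scored": len(pdgv_cadd),
        "n_background_scored": len(bg_cadd),
        "p_two_sided": cadd_p,
    }

    # --- LOH ----------------------------------------------------------------
    obs_path = bundle / "tumor_observations.tsv"
    loh_stage: dict = {}
    loh_df = pd.DataFrame()
    if obs_path.exists():
        observations = read_tumor_observations(obs_path, manifest)
        normal_vafs = {c.key: c.vaf for calls in cohort.values() for c in calls}
        pdgv_keys = {r.key for r in pdgv_result.records}
        control_calls = build_background_controls(
            [c for calls in cohort.values() for c in calls], annotations, roles
        )
        control_keys = {c.key for c in control_calls}

        pdgv_obs = [o for o in observations if o.key in pdgv_keys]
        control_obs = [o for o in observations if o.key in control_keys]
        loh_calls, removed = annotate_loh(
            pdgv_obs, normal_vafs, threshold=loh_threshold
        )
        control_passed, _ = annotate_loh(control_obs, normal_vafs, threshold=loh_threshold)
        loh_stage = {
            "n_input": len(pdgv_obs),
            "n_output": len(loh_calls),
            "removed": removed,
            "n_loh": sum(1 for c in loh_calls if c.is_loh),
            "loh_fraction": loh_fraction(loh_calls) if loh_calls else None,
        }
        if loh_calls and control_passed:
            d_stat, ks_p = compare_vaf_densities(
                [c.corrected for c in loh_calls],
                [c.corrected for c in control_passed],
            )
            loh_stage["ks_vs_controls"] = {"D": d_stat, "p": ks_p}
        # paired primary/metastatic corrected VAFs per pDGV locus
        pairs = []
        by_patient_site: dict[tuple[str, str, tuple], list[float]] = {}
        for c in loh_calls:
            o = c.observation
            by_patient_site.setdefault((o.patient_id, o.site, o.key), []).append(c.corrected)
        seen = {(p, k) for (p, s, k) in by_patient_site if s == "primary"}
        for (patient_id, key) in sorted(seen):
            pri = by_patient_site.get((patient_id, "primary", key))
            met = by_patient_site.get((patient_id, "metastatic", key))
            if pri and met:
                pairs.append((pri[0], met[0]))
        if pairs:
            frac_up, p_paired = compare_paired_primary_met(pairs)
            loh_stage["paired_primary_met"] = {
                "n_pairs": len(pairs),
                "fraction_increasing": frac_up,
                "p_two_sided": p_paired,
            }
        loh_df = pd.DataFrame([
            {
                "tumor_id": c.observation.tumor_id,
                "patient_id": c.observation.patient_id,
                "chrom": c.observation.chrom,
                "pos": c.observation.pos,
                "ref": c.observation.ref,
                "alt": c.observation.alt,
                "normal_vaf": round(c.normal_vaf, 4),
                "raw_vaf": round(c.observation.raw_vaf, 4),
                "corrected_vaf": round(c.corrected, 4),
                "ratio": round(c.ratio, 4),
                "is_loh": c.is_loh,
            }
            for c in loh_calls
        ])
    loh_df.to_csv(out / "loh.tsv", sep="\t", index=False)
    report.stages["loh"] = loh_stage

    # --- somatic consensus --------------------------------------------------
    caller_dir = bundle / "callers"
    somatic_by_tumor = {}
    somatic_stage_in = 0
    removed_total: dict[str, int] = {}
    if caller_dir.exists():
        for patient in manifest.patients:
            for tumor in patient.tumors:
                per_caller = {}
                for caller in CALLERS:
                    path = caller_dir / f"{tumor.tumor_id}.{caller}.vcf"
                    if not path.exists():
                        raise InputError(f"missing caller VCF {path}")
                    per_caller[caller] = read_caller_vcf(path, caller, tumor.tumor_id)
                consensus = merge_callers(per_caller)
                somatic_stage_in += len(consensus)
                retained, removed = apply_somatic_filters(consensus)
                for k, v in removed.items():
                    removed_total[k] = removed_total.get(k, 0) + v
                somatic_by_tumor[tumor.tumor_id] = retained
        somatic_df = pd.DataFrame([
            {
                "tumor_id": c.tumor_id, "chrom": c.chrom, "pos": c.pos,
                "ref": c.ref, "alt": c.alt,
                "callers": ",".join(sorted(c.callers)),
                "tumor_depth": c.tumor_depth, "tumor_alt": c.tumor_alt,
                "tumor_vaf": round(c.tumor_vaf, 4), "normal_vaf": c.normal_vaf,
            }
            for calls in somatic_by_tumor.values() for c in calls
        ])
        somatic_df.to_csv(out / "somatic.tsv", sep="\t", index=False)
        report.stages["somatic"] = {
            "n_input": somatic_stage_in,
            "n_output": sum(len(v) for v in somatic_by_tumor.values()),
            "removed": removed_total,
        }

    # --- germline-somatic interactions --------------------------------------
    cn_path = bundle / "cn_events.tsv"
    cn_events = read_cn_events(cn_path) if cn_path.exists() else []
    cn_by_tumor: dict[str, list] = {}
    for ev in cn_events:
        cn_by_tumor.setdefault(ev.tumor_id, []).append(ev)
    t2p = manifest.tumor_to_patient()
    gene_gsis = gene_level_gsi(
        pdgv_result.records, somatic_by_tumor, cn_by_tumor, annotations, roles, t2p
    )
    pathway_gsis = pathway_level_gsi(
        pdgv_result.records, somatic_by_tumor, cn_by_tumor, pathways,
        annotations, roles, t2p, alpha=alpha,
    )
    gsi_df = pd.DataFrame([
        {
            "level": "gene", "patient_id": g.patient_id, "tumor_id": g.tumor_id,
            "pathway_id": "", "gene_or_genes": g.gene, "somatic": g.somatic_kind,
            "p_value": "", "private": "",
        }
        for g in gene_gsis
    ] + [
        {
            "level": "pathway", "patient_id": g.patient_id, "tumor_id": g.tumor_id,
            "pathway_id": g.pathway_id,
            "gene_or_genes": ",".join(sorted(g.germline_genes | g.somatic_genes)),
            "somatic": ",".join(sorted(g.somatic_genes)),
            "p_value": round(g.p_value, 6), "private": g.private,
        }
        for g in pathway_gsis
    ])
    gsi_df.to_csv(out / "gsi.tsv", sep="\t", index=False)
    tumors_by_patient = {
        p.patient_id: [t.tumor_id for t in p.tumors] for p in manifest.patients
    }
    gsi_stage = {
        "n_gene_level": len(gene_gsis),
        "n_pathway_level": len(pathway_gsis),
        "patients_with_pathway_gsi": len({g.patient_id for g in pathway_gsis}),
    }
    if any(len(ts) >= 2 for ts in tumors_by_patient.values()) and pathway_gsis:
        gsi_stage["private_gsi_fraction"] = private_gsi_fraction(
            pathway_gsis, tumors_by_patient
        )
    report.stages["gsi"] = gsi_stage

    with open(out / "report.json", "w") as fh:
        fh.write(report.to_json())
    return report
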