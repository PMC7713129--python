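"""The synthetic cohort generator: determinism, planted truth, read models."""

import filecmp

import numpy as np
import pytest

from dgvar import (
    PROFILES,
    SimulationConfig,
    call_pdgvs,
    generate_cohort,
    loh_allele_fraction,
    read_annotation_table,
    read_gene_roles,
    read_gene_sets,
    read_manifest,
    read_vcf,
    simulate_caller_detection,
    simulate_tumor_reads,
)
from dgvar.errors import InputError
from dgvar.somatic_consensus import CALLERS, SomaticCall

from conftest import read_tsv


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        config = SimulationConfig(seed=99, n_patients=4)
        b1, _ = generate_cohort(config, tmp_path / "a")
        b2, _ = generate_cohort(config, tmp_path / "b")
        for rel in ("annotations.tsv", "gene_roles.tsv", "pathways.gmt",
                    "manifest.yaml", "tumor_observations.tsv", "truth_variants.tsv"):
            assert filecmp.cmp(b1.root / rel, b2.root / rel, shallow=False), rel
        for vcf in sorted((b1.root / "germline").iterdir()):
            assert filecmp.cmp(vcf, b2.root / "germline" / vcf.name, shallow=False)
        for vcf in sorted((b1.root / "callers").iterdir()):
            assert filecmp.cmp(vcf, b2.root / "callers" / vcf.name, shallow=False)

    def test_occupied_output_dir_rejected(self, tmp_path):
        (tmp_path / "x").mkdir()
        (tmp_path / "x" / "junk").write_text("")
        with pytest.raises(InputError):
            generate_cohort(SimulationConfig(seed=1, n_patients=2), tmp_path / "x")


class TestPlantedStructure:
    def test_truth_classes_and_counts(self, cohort_bundle):
        bundle, truth, config = cohort_bundle
        classes = set(truth.variants["class"].unique())
        assert classes <= {
            "pdgv_clinvar", "pdgv_tsg_truncating", "common_snp", "chip_like",
            "low_quality", "artifact", "rare_synonymous", "background_truncating_nonTSG",
        }
        counts = truth.variants["class"].value_counts()
        n = config.n_patients
        assert counts["background_truncating_nonTSG"] == n * config.background_variants_per_patient
        assert counts["rare_synonymous"] == n * config.rare_synonymous_per_patient
        # pDGV plants are Poisson(rate) per patient: loose 4-sigma band
        n_pdgv = counts.get("pdgv_clinvar", 0) + counts.get("pdgv_tsg_truncating", 0)
        lam = n * config.pdgv_rate
        assert abs(n_pdgv - lam) < 4 * np.sqrt(lam) + 1
        # every planted item appears exactly once
        keys = truth.variants[["patient_id", "chrom", "pos", "ref", "alt"]]
        assert not keys.duplicated().any()

    def test_artifacts_recur_above_recurrence_cap(self, cohort_bundle):
        bundle, truth, config = cohort_bundle
        artifacts = truth.variants[truth.variants["class"] == "artifact"]
        per_locus = artifacts.groupby(["chrom", "pos"])["patient_id"].nunique()
        assert (per_locus / config.n_patients > 0.05).all()

    def test_chip_vafs_subheterozygous(self, cohort_bundle):
        bundle, truth, config = cohort_bundle
        manifest = read_manifest(bundle.manifest)
        chip = truth.variants[truth.variants["class"] == "chip_like"]
        for patient_id, grp in chip.groupby("patient_id"):
            calls = {c.key: c for c in read_vcf(
                bundle.germline_dir / f"{patient_id}.vcf", patient_id)}
            for row in grp.itertuples(index=False):
                vaf = calls[(row.chrom, int(row.pos), row.ref, row.alt)].vaf
                assert 0.05 < vaf < 0.35

    def test_cascade_recovers_planted_truth_exactly(self, cohort_bundle):
        bundle, truth, config = cohort_bundle
        manifest = read_manifest(bundle.manifest)
        annotations = read_annotation_table(bundle.annotations)
        roles = read_gene_roles(bundle.gene_roles)
        cohort = {
            p.patient_id: read_vcf(bundle.germline_dir / f"{p.patient_id}.vcf", p.patient_id)
            for p in manifest.patients
        }
        result = call_pdgvs(cohort, annotations, roles, PROFILES["wcm"])
        called = {(r.patient_id, r.key) for r in result.records}
        assert called == truth.pdgv_truth()
        assert result.conserved()

    def test_pathway_file_covers_gene_roles(self, cohort_bundle):
        bundle, _, _ = cohort_bundle
        pathways = read_gene_sets(bundle.pathways)
        roles = read_gene_roles(bundle.gene_roles)
        assert len(pathways) > 0
        assert pathways.genes() & roles.genes()


class TestTumorReadModel:
    @pytest.mark.parametrize(
        "purity,loh,model,expected_q",
        [
            (1.0, True, "copy_neutral", 1.0),
            (0.6, True, "copy_neutral", 0.8),
            (0.6, False, "copy_neutral", 0.5),
            (1.0, True, "deletion", 1.0),
            (0.5, True, "deletion", 1 / 1.5),
        ],
    )
    def test_expected_allele_fraction(self, purity, loh, model, expected_q):
        assert loh_allele_fraction(purity, loh, model) == pytest.approx(expected_q)
        rng = np.random.default_rng(3)
        draws = [simulate_tumor_reads(purity, loh, model, 500, rng)[1] / 500
                 for _ in range(200)]
        assert np.mean(draws) == pytest.approx(expected_q, abs=0.01)

    def test_bad_model_rejected(self):
        with pytest.raises(InputError):
            simulate_tumor_reads(0.5, True, "nonsense", 50, np.random.default_rng(0))

    def test_corrected_vaf_clamps_at_moderate_purity(self):
        # purity 0.6 copy-neutral: expected raw 0.8, corrected clamps to 1.0
        from dgvar import corrected_vaf

        assert corrected_vaf(0.8, 0.6) == 1.0


class TestCallerSimulation:
    def _variants(self, n, indel_every=0):
        out = []
        for i in range(n):
            ref, alt = ("AT", "A") if indel_every and i % indel_every == 0 else ("A", "T")
            out.append(SomaticCall(
                tumor_id="T1", chrom="chr1", pos=10 + 97 * i, ref=ref, alt=alt,
                callers=frozenset(CALLERS), tumor_depth=80, tumor_alt=30, normal_vaf=0.0,
            ))
        return out

    def test_perfect_sensitivity_perfect_recall(self):
        from dgvar import merge_callers

        variants = self._variants(50)
        per_caller = simulate_caller_detection(
            variants, {c: 1.0 for c in CALLERS}, np.random.default_rng(0)
        )
        assert len(merge_callers(per_caller)) == 50

    def test_single_caller_false_positive_removed(self):
        from dgvar import merge_callers

        variants = self._variants(5)

        def fp_factory(rng, caller, i):
            # private loci: distinct per caller, never shared
            return SomaticCall(
                tumor_id="T1", chrom="chr2",
                pos=1000 + 100 * CALLERS.index(caller) + i, ref="A", alt="G",
                callers=frozenset({caller}), tumor_depth=60, tumor_alt=20,
                normal_vaf=0.0,
            )

        per_caller = simulate_caller_detection(
            variants, {c: 1.0 for c in CALLERS}, np.random.default_rng(1),
            fp_rate=2.0, fp_factory=fp_factory,
        )
        merged = merge_callers(per_caller)
        assert {c.chrom for c in merged} == {"chr1"}  # no chr2 false positive survives

    def test_recall_matches_binomial_tail(self):
        """sensitivity 0.9 each: P(>=2 of 4 detect) = 0.9963."""
        from dgvar import merge_callers

        variants = self._variants(1000)
        per_caller = simulate_caller_detection(
            variants, {c: 0.9 for c in CALLERS}, np.random.default_rng(7)
        )
        recall = len(merge_callers(per_caller)) / 1000
        expected = 1 - 0.1**4 - 4 * 0.9 * 0.1**3
        assert recall == pytest.approx(expected, abs=0.01)

    def test_indels_restricted_to_two_callers(self):
        variants = self._variants(30, indel_every=1)
        per_caller = simulate_caller_detection(
            variants, {c: 1.0 for c in CALLERS}, np.random.default_rng(2)
        )
        assert per_caller["mutect2"] == [] and per_caller["somaticsniper"] == []
        assert len(per_caller["strelka"]) == 30
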