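"""Pathway scoring, hypergeometric ORA, and germline-somatic interactions."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from dgvar import (
    AnnotationStore,
    Pathway,
    PathwayCollection,
    PathwayScoreInput,
    enrichment_score,
    gene_level_gsi,
    ora_test,
    pathway_level_gsi,
    private_gsi_fraction,
)
from dgvar.dgvar_core import PDGVRecord
from dgvar.errors import InputError
from dgvar.gsi_pathways import PathwayGSI, qualifying_somatic_genes

from conftest import ann, call
from test_somatic_consensus import consensus


class TestEnrichmentScore:
    @pytest.mark.parametrize(
        "k,m,K,expected",
        [
            (2, 4, 50, math.log10(11)),
            (0, 4, 50, 0.0),
            (1, 1, 1000, math.log10(2)),
        ],
    )
    def test_formula(self, k, m, K, expected):
        assert enrichment_score(PathwayScoreInput(k, m, K)) == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(InputError):
            enrichment_score(PathwayScoreInput(0, 0, 10))

    @settings(max_examples=60, deadline=None)
    @given(st.integers(1, 20), st.integers(1, 50), st.integers(1, 500))
    def test_monotonicity(self, k, m_extra, K_extra):
        m = k + m_extra
        K = k + K_extra
        s = enrichment_score(PathwayScoreInput(k, m, K))
        assert s >= 0
        assert enrichment_score(PathwayScoreInput(k - 1, m, K)) <= s  # fewer hits
        assert enrichment_score(PathwayScoreInput(k, m + 1, K)) < s
        assert enrichment_score(PathwayScoreInput(k, m, K + 1)) < s


def hypergeom_tail_oracle(overlap, n_universe, n_pathway, n_query):
    """Oracle: direct summation of the hypergeometric pmf upper tail."""
    total = comb(n_universe, n_query, exact=True)
    p = 0
    for x in range(overlap, min(n_pathway, n_query) + 1):
        p += comb(n_pathway, x, exact=True) * comb(
            n_universe - n_pathway, n_query - x, exact=True
        )
    return p / total


class TestOra:
    def test_full_overlap(self):
        universe = {f"G{i}" for i in range(20)}
        pathway = {f"G{i}" for i in range(5)}
        p = ora_test(pathway, pathway, universe)
        assert p == pytest.approx(1 / comb(20, 5, exact=True))

    def test_zero_overlap_is_one(self):
        universe = {f"G{i}" for i in range(10)}
        assert ora_test({"G0"}, {"G9"}, universe) == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(5, 50), st.data())
    def test_matches_pmf_summation(self, n_universe, data):
        n_pathway = data.draw(st.integers(1, n_universe))
        n_query = data.draw(st.integers(1, n_universe))
        universe = {f"G{i}" for i in range(n_universe)}
        pathway = {f"G{i}" for i in range(n_pathway)}
        max_overlap = min(n_pathway, n_query)
        overlap = data.draw(st.integers(max(0, n_query - (n_universe - n_pathway)),
                                        max_overlap))
        query = {f"G{i}" for i in range(overlap)} | {
            f"G{n_pathway + i}" for i in range(n_query - overlap)
        }
        assert len(query) == n_query
        assert ora_test(query, pathway, universe) == pytest.approx(
            hypergeom_tail_oracle(overlap, n_universe, n_pathway, n_query)
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            ora_test(set(), set(), set())


def pdgv(patient="P1", gene="TSG001", pos=100):
    return PDGVRecord(patient, call(sample=patient, pos=pos), gene, "TSG",
                      "tsg_truncating", ())


class TestGeneLevel:
    def _setup(self, roles):
        store = AnnotationStore([
            ann(pos=200, gene="TSG001", effect="stop_gained"),
            ann(pos=300, gene="TSG001", effect="missense"),
        ])
        return store, {"T1": "P1"}

    def test_cn_loss_gsi(self, roles):
        store, t2p = self._setup(roles)
        from dgvar import CopyNumberEvent

        out = gene_level_gsi([pdgv()], {}, {"T1": [CopyNumberEvent("T1", "TSG001", "loss")]},
                             store, roles, t2p)
        assert len(out) == 1 and out[0].somatic_kind == "cn_loss"

    def test_truncating_somatic_gsi_and_missense_rejected(self, roles):
        store, t2p = self._setup(roles)
        trunc = consensus(pos=200)
        missense = consensus(pos=300)
        out = gene_level_gsi([pdgv()], {"T1": [trunc]}, {}, store, roles, t2p)
        assert [(g.gene, g.somatic_kind) for g in out] == [("TSG001", "truncating_mutation")]
        assert gene_level_gsi([pdgv()], {"T1": [missense]}, {}, store, roles, t2p) == []

    def test_no_somatic_event_no_gsi(self, roles):
        store, t2p = self._setup(roles)
        assert gene_level_gsi([pdgv()], {}, {}, store, roles, t2p) == []


class TestPathwayLevel:
    def _fixture(self, roles):
        # universe of 30 genes; pathway P1 = {TSG001, ONC001, X1}; P2 decoy
        universe = {f"X{i}" for i in range(27)} | {"TSG001", "TSG002", "ONC001"}
        pathways = PathwayCollection([
            Pathway("P1", "hit pathway", frozenset({"TSG001", "ONC001", "X1"})),
            Pathway("P2", "germline only", frozenset({"TSG002", "X2", "X3"})),
        ])
        store = AnnotationStore([
            ann(pos=400, gene="ONC001", effect="missense"),
        ])
        return universe, pathways, store

    def test_detects_germline_plus_somatic_pathway(self, roles):
        universe, pathways, store = self._fixture(roles)
        somatic = {"T1": [consensus(pos=400)]}
        out = pathway_level_gsi(
            [pdgv(gene="TSG001"), pdgv(gene="TSG002", pos=150)], somatic, {},
            pathways, store, roles, {"T1": "P1"}, universe=universe,
        )
        assert [g.pathway_id for g in out] == ["P1"]
        assert out[0].germline_genes == {"TSG001"}
        assert out[0].somatic_genes == {"ONC001"}
        # P2 has no somatic hit -> not a GSI even if enriched

    def test_alpha_is_strict(self, roles):
        universe, pathways, store = self._fixture(roles)
        somatic = {"T1": [consensus(pos=400)]}
        args = ([pdgv(gene="TSG001")], somatic, {}, pathways, store, roles,
                {"T1": "P1"})
        out = pathway_level_gsi(*args, universe=universe, alpha=0.05)
        p = out[0].p_value if out else None
        if p is not None:
            # re-running with alpha exactly at the observed p drops the hit
            assert pathway_level_gsi(*args, universe=universe, alpha=p) == []

    def test_identical_gene_sets_merged(self, roles):
        universe, _, store = self._fixture(roles)
        pathways = PathwayCollection([
            Pathway("KEGG_A", "a", frozenset({"TSG001", "ONC001"})),
            Pathway("REACTOME_A", "a", frozenset({"TSG001", "ONC001"})),
        ])
        out = pathway_level_gsi(
            [pdgv(gene="TSG001")], {"T1": [consensus(pos=400)]}, {},
            pathways, store, roles, {"T1": "P1"}, universe=universe,
        )
        assert [g.pathway_id for g in out] == ["KEGG_A|REACTOME_A"]

    def test_oncogene_truncation_does_not_qualify(self, roles):
        store = AnnotationStore([ann(pos=500, gene="ONC001", effect="frameshift")])
        genes = qualifying_somatic_genes([consensus(pos=500, ref="AT", alt="A")], [],
                                         store, roles)
        assert genes == set()


class TestPrivateFraction:
    def _gsi(self, patient, tumor, pathway):
        return PathwayGSI(patient, tumor, pathway, frozenset({"g"}), frozenset({"s"}),
                          0.01)

    def test_half_private(self):
        gsis = [
            self._gsi("P1", "T1", "PW1"),
            self._gsi("P1", "T1", "PW2"),
            self._gsi("P1", "T2", "PW2"),
        ]
        assert private_gsi_fraction(gsis) == pytest.approx(0.5)

    def test_identical_sets_give_zero(self):
        gsis = [self._gsi("P1", "T1", "PW1"), self._gsi("P1", "T2", "PW1")]
        assert private_gsi_fraction(gsis) == 0.0

    def test_single_tumor_patients_excluded_from_denominator(self):
        gsis = [self._gsi("P1", "T1", "PW1"), self._gsi("P1", "T2", "PW2"),
                self._gsi("P2", "T3", "PW3")]
        tumors = {"P1": ["T1", "T2"], "P2": ["T3"]}
        assert private_gsi_fraction(gsis, tumors) == pytest.approx(1.0)
        with pytest.raises(InputError):
            private_gsi_fraction([self._gsi("P2", "T3", "PW3")], {"P2": ["T3"]})
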