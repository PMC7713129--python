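"""The pDGV filter cascade: rules, boundaries, traces, and a naive oracle."""

import dataclasses
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from dgvar import (
    AnnotationStore,
    FilterProfile,
    PROFILES,
    apply_quality_filters,
    call_pdgvs,
    classify_variant,
    extract_rare_synonymous,
    flag_alignment_clusters,
)

from conftest import ann, call


WCM = PROFILES["wcm"]


def make_roles():
    from dgvar import GeneRoleTable

    t = GeneRoleTable()
    t.set_role("TSG001", "TSG")
    t.set_role("TSG002", "TSG")
    t.set_role("ONC001", "oncogene")
    return t


class TestQualityFilters:
    @pytest.mark.parametrize(
        "profile_name,qual,depth,vaf,kept,failing",
        [
            ("wcm", 49.9, 60, 0.50, False, "site_quality"),  # "lower than 50" removed
            ("wcm", 50.0, 10, 0.35, True, None),  # boundary values retained
            ("wcm", 99.0, 9, 0.50, False, "depth"),
            ("wcm", 99.0, 60, 0.34, False, "vaf"),  # sub-het VAF: possible CHIP
            ("spark", 30.0, 8, 0.20, True, None),  # SPARK boundary retained
            ("spark", 29.9, 8, 0.20, False, "site_quality"),
        ],
    )
    def test_thresholds_and_boundaries(self, profile_name, qual, depth, vaf, kept, failing):
        profile = PROFILES[profile_name]
        c = call(qual=qual, depth=depth, alt_depth=round(vaf * depth))
        retained, trace = apply_quality_filters([c], profile)
        assert (len(retained) == 1) is kept
        if failing:
            entries = dict(trace[0][1])
            assert entries[failing] is False

    def test_empty_input(self):
        retained, trace = apply_quality_filters([], WCM)
        assert retained == [] and trace == []


def naive_cluster_flags(calls, window, min_count):
    """Oracle: try every genomic interval of span <= window."""
    snvs = [c for c in calls if len(c.ref) == 1 and len(c.alt) == 1]
    flagged = set()
    for c in snvs:
        for start in range(c.pos - window + 1, c.pos + 1):
            members = [
                s for s in snvs
                if s.chrom == c.chrom and start <= s.pos <= start + window - 1
            ]
            if c in members and len(members) >= min_count:
                flagged.add(c)
                break
    return flagged


class TestAlignmentClusters:
    @pytest.mark.parametrize(
        "positions,expected_flagged",
        [
            ((100, 104, 108), {100, 104, 108}),  # span 9 <= 10
            ((100, 105, 120), set()),
            ((100,), set()),
            ((100, 105, 109), {100, 105, 109}),  # span exactly 10, inclusive
            ((100, 105, 110), set()),  # span 11: just outside the window
        ],
    )
    def test_known_windows(self, positions, expected_flagged):
        calls = [call(pos=p) for p in positions]
        flagged = {c.pos for c in flag_alignment_clusters(calls, 10, 3)}
        assert flagged == expected_flagged

    def test_indels_never_flagged(self):
        calls = [call(pos=p, ref="AT", alt="A") for p in (100, 102, 104)]
        assert flag_alignment_clusters(calls, 10, 3) == set()

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(1, 60), min_size=0, max_size=12, unique=True),
        st.integers(2, 12),
        st.integers(2, 4),
    )
    def test_matches_sliding_window_oracle(self, positions, window, min_count):
        calls = [call(pos=p) for p in positions]
        assert flag_alignment_clusters(calls, window, min_count) == naive_cluster_flags(
            calls, window, min_count
        )


class TestClassifyVariant:
    def test_tsg_truncation_with_population_qc(self, roles):
        a = ann(effect="stop_gained", gene="TSG001")
        assert classify_variant(call(), a, roles) == "tsg_truncating"
        bad = dataclasses.replace(a, inbreeding_pass=False)
        assert classify_variant(call(), bad, roles) == "neutral"
        no_qc = classify_variant(call(), bad, roles, require_exac_qc=False)
        assert no_qc == "tsg_truncating"

    def test_benign_and_noncancer_pathogenic(self, roles):
        benign = ann(effect="missense", clinvar_class="likely_benign")
        assert classify_variant(call(), benign, roles) == "clinvar_benign"
        noncancer = ann(effect="missense", clinvar_class="pathogenic", condition=False,
                        gene="NEU001")
        assert classify_variant(call(), noncancer, roles) == "neutral"
        unknown = dataclasses.replace(noncancer, clinvar_condition_is_cancer=None)
        assert classify_variant(call(), unknown, roles) == "clinvar_pathogenic"

    def test_both_and_restrict_to_tsg(self, roles):
        both = ann(effect="frameshift", gene="TSG001", clinvar_class="pathogenic",
                   condition=True)
        assert classify_variant(call(), both, roles) == "both"
        outside = ann(effect="missense", gene="NEU001", clinvar_class="pathogenic",
                      condition=True)
        assert classify_variant(call(), outside, roles) == "clinvar_pathogenic"
        assert classify_variant(call(), outside, roles, restrict_to_tsg=True) == "neutral"

    def test_non_tsg_truncation_is_neutral(self, roles):
        a = ann(effect="frameshift", gene="NEU001")
        assert classify_variant(call(), a, roles) == "neutral"


def naive_pdgv_oracle(cohort, annotations, roles, profile, exclusion=frozenset()):
    """Independent re-evaluation of every rule, variant by variant."""
    n = len(cohort)
    carriers = {}
    for pid, calls in cohort.items():
        for c in calls:
            carriers.setdefault(c.key, set()).add(pid)
    kept = set()
    for pid, calls in cohort.items():
        if profile.snv_cluster_min_count is not None:
            flagged = naive_cluster_flags(
                calls, profile.snv_cluster_window, profile.snv_cluster_min_count
            )
        else:
            flagged = set()
        for c in calls:
            a = annotations.get(c.key)
            cls = classify_variant(c, a, roles, profile.require_exac_qc,
                                   profile.restrict_to_tsg)
            if (
                c.site_quality >= profile.min_site_quality
                and c.depth >= profile.min_depth
                and c.vaf >= profile.min_vaf
                and c not in flagged
                and a.pop_af <= profile.max_pop_af
                and cls in ("clinvar_pathogenic", "tsg_truncating", "both")
                and len(carriers[c.key]) / n <= profile.cohort_recurrence_max
                and c.key not in exclusion
            ):
                kept.add((pid, c.key))
    return kept


def small_cohorts():
    """Strategy: up to 5 patients x up to 12 annotated variants."""
    variant = st.tuples(
        st.integers(1, 40),  # pos
        st.floats(30, 110),  # quality
        st.integers(5, 80),  # depth
        st.floats(0.1, 0.9),  # vaf target
        st.sampled_from(["stop_gained", "frameshift", "missense", "synonymous"]),
        st.sampled_from(["TSG001", "TSG002", "NEU001", "ONC001"]),
        st.sampled_from(["absent", "pathogenic", "likely_benign", "vus"]),
        st.floats(0, 0.03),  # pop_af
        st.booleans(),  # inbreeding_pass
    )
    return st.lists(
        st.lists(variant, min_size=0, max_size=12, unique_by=lambda v: v[0]),
        min_size=1,
        max_size=5,
    )


class TestCascade:
    def _build(self, patient_variants):
        store = AnnotationStore()
        cohort = {}
        seen = set()
        for i, variants in enumerate(patient_variants):
            pid = f"P{i + 1}"
            calls = []
            for pos, qual, depth, vaf, effect, gene, clinvar, pop_af, inb in variants:
                key = ("chr1", pos, "A", "T")
                if key not in seen:
                    seen.add(key)
                    store.add(ann(pos=pos, gene=gene, effect=effect,
                                  clinvar_class=clinvar, condition=True,
                                  pop_af=round(pop_af, 4), inbreeding_pass=inb))
                calls.append(call(sample=pid, pos=pos, qual=round(qual, 1),
                                  depth=depth, alt_depth=round(vaf * depth)))
            cohort[pid] = calls
        return cohort, store

    @settings(max_examples=60, deadline=None)
    @given(small_cohorts())
    def test_matches_naive_oracle(self, patient_variants):
        roles = make_roles()
        cohort, store = self._build(patient_variants)
        result = call_pdgvs(cohort, store, roles, WCM)
        got = {(r.patient_id, r.key) for r in result.records}
        assert got == naive_pdgv_oracle(cohort, store, roles, WCM)
        assert result.conserved()
        for r in result.records:
            assert all(ok for _, ok in r.filter_trace)
        for _, _, reason in result.removed:
            assert reason in dict.fromkeys(
                ["site_quality", "depth", "vaf", "snv_cluster", "pop_af",
                 "classification", "cohort_recurrence", "exclusion_list"]
            )

    @settings(max_examples=40, deadline=None)
    @given(small_cohorts(), st.sampled_from([
        {"min_site_quality": 60.0},
        {"min_depth": 20},
        {"min_vaf": 0.45},
        {"max_pop_af": 0.002},
        {"cohort_recurrence_max": 0.01},
    ]))
    def test_tightening_is_monotone(self, patient_variants, override):
        roles = make_roles()
        cohort, store = self._build(patient_variants)
        base = call_pdgvs(cohort, store, roles, WCM).n_retained
        tightened = dataclasses.replace(WCM, **override)
        assert call_pdgvs(cohort, store, roles, tightened).n_retained <= base

    def test_result_independent_of_input_order(self, roles):
        cohort, store = self._build([
            [(5, 99, 60, 0.5, "stop_gained", "TSG001", "absent", 0.0, True),
             (9, 99, 60, 0.5, "frameshift", "TSG002", "absent", 0.001, True)],
        ])
        fwd = call_pdgvs(cohort, store, roles, WCM)
        rev = call_pdgvs({p: list(reversed(c)) for p, c in cohort.items()}, store, roles, WCM)
        assert {(r.patient_id, r.key) for r in fwd.records} == {
            (r.patient_id, r.key) for r in rev.records
        }

    def test_recurrent_variant_removed_as_artifact(self, roles):
        store = AnnotationStore()
        store.add(ann(pos=7, gene="TSG001", effect="stop_gained"))
        shared = lambda pid: call(sample=pid, pos=7)
        cohort = {f"P{i}": [shared(f"P{i}")] for i in range(40)}
        kept_cohort = {"P0": cohort["P0"], **{f"Q{i}": [] for i in range(39)}}
        # carried by 3/40 patients (7.5% > 5%) -> filtered
        three = {f"P{i}": [shared(f"P{i}")] if i < 3 else [] for i in range(40)}
        res = call_pdgvs(three, store, roles, WCM)
        assert res.n_retained == 0
        assert res.removal_counts["cohort_recurrence"] == 3
        # carried by 1/40 -> retained, and 2/40 (exactly 5%) also retained
        assert call_pdgvs(kept_cohort, store, roles, WCM).n_retained == 1

    def test_exclusion_list(self, roles):
        store = AnnotationStore()
        store.add(ann(pos=7, gene="TSG001", effect="stop_gained"))
        cohort = {"P1": [call(pos=7)], **{f"Q{i}": [] for i in range(20)}}
        res = call_pdgvs(cohort, store, roles, WCM,
                         exclusion_list=frozenset({("chr1", 7, "A", "T")}))
        assert res.n_retained == 0
        assert res.removal_counts["exclusion_list"] == 1


class TestRareSynonymous:
    def _cohort(self, store_rows):
        store = AnnotationStore()
        calls = []
        for pos, effect, pop_af in store_rows:
            store.add(ann(pos=pos, gene="NEU001", effect=effect, pop_af=pop_af))
            calls.append(call(pos=pos, qual=80, depth=40, alt_depth=20))
        return {"P1": calls, **{f"Q{i}": [] for i in range(20)}}, store

    def test_rules(self):
        cohort, store = self._cohort([
            (5, "synonymous", 0.005),   # retained
            (25, "synonymous", 0.02),   # too common
            (45, "missense", 0.001),    # wrong effect class
            (65, "synonymous", 0.01),   # exactly 1%: "<1%" is strict
        ])
        res = extract_rare_synonymous(cohort, store, WCM)
        assert [r.call.pos for r in res.records] == [5]
        assert res.conserved()

    def test_same_qc_as_pdgvs(self):
        cohort, store = self._cohort([(5, "synonymous", 0.001)])
        low_vaf = call(pos=105, qual=80, depth=40, alt_depth=10)  # vaf 0.25
        store.add(ann(pos=105, gene="NEU001", effect="synonymous", pop_af=0.001))
        cohort["P1"].append(low_vaf)
        res = extract_rare_synonymous(cohort, store, WCM)
        assert [r.call.pos for r in res.records] == [5]
        assert res.removal_counts["vaf"] == 1
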