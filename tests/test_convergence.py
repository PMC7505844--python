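"""Motif enumeration, naive-reference enrichment and convergence grouping."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synovitcr import convergence
from synovitcr.convergence import GliphInputSet, GliphSequence
from synovitcr.errors import UsageError

AA = "ACDEFGHIKLMNPQRSTVY"  # W reserved for planted motifs in these tests


def seq(cdr3, patient="P01", v="TRBV28", j="TRBJ1-1", cells=1):
    return GliphSequence(f"{patient}:{v}:{j}:{cdr3}", cdr3, v, j, patient, cells)


class TestPrepareInput:
    def test_two_beta_partition_emits_suffixed_variants(self, partition_factory):
        part = partition_factory("BC1", ["CAVNYQLIW"], ["CASSAAF", "CASSGGF"])
        gliph = convergence.prepare_gliph_input([part], ["CASSNQNTEAFF"])
        suffixes = sorted(s.seq_id.rsplit("-", 1)[-1] for s in gliph.sequences)
        assert suffixes == ["v1", "v2"]

    def test_alpha_only_partitions_dropped_with_counter(self, partition_factory):
        parts = [partition_factory("BC1", ["CAVNYQLIW"], []),
                 partition_factory("BC2", [], ["CASSAAF"])]
        report = {}
        gliph = convergence.prepare_gliph_input(parts, ["CASSNQNTEAFF"],
                                                report=report)
        assert report["alpha_only_dropped"] == 1
        assert len(gliph.sequences) == 1

    def test_identical_betas_aggregate_cell_counts(self, partition_factory):
        parts = [partition_factory(f"BC{i}", ["CAVNYQLIW"], ["CASSAAF"])
                 for i in range(3)]
        gliph = convergence.prepare_gliph_input(parts, ["CASSNQNTEAFF"])
        (entry,) = gliph.sequences
        assert entry.source_cells == 3

    def test_empty_reference_rejected(self, partition_factory):
        with pytest.raises(UsageError):
            convergence.prepare_gliph_input(
                [partition_factory("BC1", [], ["CASSAAF"])], [])


class TestMotifEnumeration:
    def test_interior_enumeration_worked_example(self):
        counts = convergence.enumerate_motifs(["CASSNQNTEAFF"], k_values=(4,),
                                              flank_trim=3)
        assert counts == {"SNQN": 1, "NQNT": 1, "QNTE": 1}

    def test_duplicate_motif_within_one_cdr3_counted_once(self):
        counts = convergence.enumerate_motifs(["CASSGGGGGGAFF"], k_values=(2,),
                                              flank_trim=3)
        assert counts["GG"] == 1

    def test_empty_set_and_too_short_sequences(self):
        assert convergence.enumerate_motifs([]) == {}
        assert convergence.enumerate_motifs(["CASSF"], k_values=(4,),
                                            flank_trim=3) == {}

    @given(st.lists(st.text(AA, min_size=1, max_size=16), min_size=0, max_size=12),
           st.sampled_from([2, 3, 4]), st.integers(0, 3))
    @settings(derandomize=True, max_examples=120)
    def test_matches_bruteforce_substring_oracle(self, seqs, k, trim):
        counts = convergence.enumerate_motifs(seqs, k_values=(k,), flank_trim=trim)
        oracle = {}
        for s in seqs:
            core = s[trim: len(s) - trim] if len(s) > 2 * trim else ""
            for motif in {core[i: i + k] for i in range(max(0, len(core) - k + 1))}:
                oracle[motif] = oracle.get(motif, 0) + 1
        assert counts == oracle


class TestGlobalEdges:
    def test_distance_one_same_length(self):
        edges = convergence.global_edges([seq("CASSNQNTEAFF"),
                                          seq("CASSNQNTEAYF")])
        assert len(edges) == 1

    def test_identical_sequences_from_different_patients(self):
        edges = convergence.global_edges([seq("CASSNQNTEAFF", patient="P01"),
                                          seq("CASSNQNTEAFF", patient="P02")])
        assert len(edges) == 1

    def test_length_mismatch_never_links(self):
        edges = convergence.global_edges([seq("CASSNQNTEAF"),
                                          seq("CASSNQNTEAFF")])
        assert edges == []


def _fold10_input():
    """100 distinct sample CDR3s (10 carrying WGWG) against a reference with
    exactly 100 carriers among 10,000 — fold change exactly 10."""
    carriers = [f"CASS{a}WGWGEAFF" for a in AA[:10]]
    background = [f"CASS{a}{b}GGGEAFF" for a in AA for b in AA][:90]
    reference = ["CASSAWGWGEAFF"] * 100 + ["CASSAGGGGEAFF"] * 9900
    return GliphInputSet([seq(s) for s in carriers + background], reference)


class TestMotifEnrichment:
    def test_configured_fold_change_is_exact(self):
        results = convergence.motif_enrichment(_fold10_input(), k_values=(4,),
                                               n_subsamples=200, seed=11)
        wgwg = next(m for m in results if m.motif == "WGWG")
        assert wgwg.observed_freq == pytest.approx(0.10)
        assert wgwg.reference_freq == pytest.approx(0.01)
        assert wgwg.fold_change == pytest.approx(10.0)
        assert wgwg.p_resampled == 1 / 200  # carriers cannot reach 10/100 by chance

    def test_motif_absent_from_reference_hits_the_floor(self):
        sample = GliphInputSet([seq("CASSAWWWWEAFF"), seq("CASSGGGGGEAFF")],
                               ["CASSAGGGGEAFF"] * 50)
        results = convergence.motif_enrichment(sample, k_values=(4,),
                                               n_subsamples=200, seed=3)
        wwww = next(m for m in results if m.motif == "WWWW")
        assert wwww.fold_change == math.inf
        assert wwww.p_resampled == 1 / 200

    def test_seed_reproducibility_and_reference_size_guard(self):
        sample = _fold10_input()
        a = convergence.motif_enrichment(sample, n_subsamples=50, seed=5)
        b = convergence.motif_enrichment(sample, n_subsamples=50, seed=5)
        assert a == b
        with pytest.raises(UsageError):
            convergence.motif_enrichment(
                GliphInputSet([seq("CASSAWWWWEAFF")], []), n_subsamples=10, seed=0)

    def test_invalid_subsample_count_rejected(self):
        with pytest.raises(ValueError):
            convergence.motif_enrichment(_fold10_input(), n_subsamples=0, seed=0)


class TestConvergenceGroups:
    def test_planted_motif_carriers_form_one_group(self):
        sample = _fold10_input()
        motifs = convergence.motif_enrichment(sample, k_values=(4,),
                                              n_subsamples=1000, seed=2)
        groups = convergence.build_convergence_groups(sample.sequences, motifs)
        carrier_ids = {s.seq_id for s in sample.sequences if "WGWG" in s.cdr3_aa}
        assert any(carrier_ids <= g.members for g in groups)

    def test_dissimilar_sequences_without_motifs_yield_no_groups(self):
        sequences = [seq("CASSAADDEAFF"), seq("CASSGGHHEAFF"),
                     seq("CASSKKLLEAFF")]
        assert convergence.build_convergence_groups(sequences, []) == []

    def test_cross_patient_groups_track_patients(self):
        sequences = [seq("CASSNQNTEAFF", patient="P01"),
                     seq("CASSNQNTEAFF", patient="P02"),
                     seq("CASSNQNTEAFF", patient="P03")]
        groups = convergence.build_convergence_groups(sequences, [])
        (group,) = groups
        assert group.patients_represented == {"P01", "P02", "P03"}

    def test_unrelated_sequence_leaves_existing_memberships_unchanged(self):
        sample = _fold10_input()
        motifs = convergence.motif_enrichment(sample, k_values=(4,),
                                              n_subsamples=500, seed=9)
        baseline = convergence.build_convergence_groups(sample.sequences, motifs)
        extra = GliphInputSet(sample.sequences + [seq("CAIMKKPPLLDTQYF")],
                              sample.reference)
        motifs2 = convergence.motif_enrichment(extra, k_values=(4,),
                                               n_subsamples=500, seed=9)
        with_extra = convergence.build_convergence_groups(extra.sequences, motifs2)
        assert ({g.members for g in baseline} == {g.members for g in with_extra})

    def test_deterministic_ordering_by_size_then_member(self):
        sequences = [seq("CASSNQNTEAFF", patient=p) for p in ("P01", "P02")] \
            + [seq("CASSYGYTEAFF", patient=p) for p in ("P01", "P02", "P03")]
        groups = convergence.build_convergence_groups(sequences, [])
        assert [g.crg_id for g in groups] == ["CRG-1", "CRG-2"]
        assert len(groups[0].members) == 3
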