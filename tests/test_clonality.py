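"""Clonotype keys, Fisher/BH statistics, enrichment calls and cluster association."""
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from synovitcr import clonality
from synovitcr.errors import UsageError
from synovitcr.experiments import fisher_p_by_enumeration
from synovitcr.synthetic_data import _biased_cluster_probs

from conftest import make_partition, nt_of


class TestFisherExact:
    def test_clone_absent_everywhere(self):
        odds, p = clonality.fisher_exact_2x2((0, 50, 0, 50))
        assert p == 1.0 and math.isnan(odds)

    def test_worked_table_matches_enumeration(self):
        odds, p = clonality.fisher_exact_2x2((10, 90, 1, 99))
        assert odds == 11.0
        assert p == pytest.approx(fisher_p_by_enumeration((10, 90, 1, 99)),
                                  rel=1e-9)

    def test_zero_cell_odds_ratios(self):
        assert clonality.fisher_exact_2x2((5, 0, 0, 5))[0] == math.inf
        assert math.isnan(clonality.fisher_exact_2x2((0, 5, 0, 5))[0])
        assert clonality.cross_product_odds_ratio((5, 0, 0, 5), haldane=True) \
            == pytest.approx(11 * 11)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            clonality.fisher_exact_2x2((-1, 2, 3, 4))

    @given(st.tuples(*[st.integers(0, 10)] * 4))
    @settings(derandomize=True, max_examples=150)
    def test_agrees_with_scipy_and_is_symmetric(self, table):
        a, b, c, d = table
        odds, p = clonality.fisher_exact_2x2(table)
        p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert p == pytest.approx(p_scipy, rel=1e-6, abs=1e-12)
        odds_swap, p_swap = clonality.fisher_exact_2x2((c, d, a, b))
        assert p_swap == pytest.approx(p, rel=1e-12)
        if math.isfinite(odds) and odds > 0:
            assert odds_swap == pytest.approx(1 / odds)


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert clonality.bh_adjust([0.05]) == [0.05]

    def test_step_up_worked_example(self):
        assert clonality.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_domain_check(self):
        with pytest.raises(ValueError):
            clonality.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=100)
    def test_output_bounds_monotonicity_and_statsmodels_agreement(self, p):
        adjusted = clonality.bh_adjust(p)
        assert all(a >= x for a, x in zip(adjusted, p))
        assert all(a <= 1.0 for a in adjusted)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(np.asarray(adjusted)[order]) >= -1e-12)
        reference = multipletests(p, method="fdr_bh")[1]
        assert adjusted == pytest.approx(reference.tolist(), abs=1e-12)


_DIGIT_AA = "ACDEFGHIKL"  # decimal digit -> residue, for synthetic clone CDR3s


def _code(i):
    return "".join(_DIGIT_AA[int(ch)] for ch in str(i))


def _partitions_for_counts(counts_by_sample, patient="P01"):
    """One partition per cell; clone i gets a unique alpha/beta CDR3 pair."""
    parts = []
    for sample, clone_counts in counts_by_sample.items():
        cell = 0
        for clone_idx, n in clone_counts.items():
            for _ in range(n):
                cell += 1
                parts.append(make_partition(
                    f"{sample}-BC{cell:05d}", [f"AA{_code(clone_idx)}"],
                    [f"SS{_code(clone_idx)}"], patient=patient, sample=sample))
    return parts


class TestAssignClonotypes:
    def test_same_chains_one_clone(self, partition_factory):
        parts = [partition_factory(f"BC{i}", ["CAVNYQLIW"], ["CASSNQNTEAFF"])
                 for i in range(2)]
        table = clonality.assign_clonotypes(parts)
        assert len(table.clones) == 1 and table.clones[0].size == 2

    def test_alpha_order_invariance(self, partition_factory):
        p1 = partition_factory("BC1", ["CAVAAF", "CAVGGF"], ["CASSNQNTEAFF"])
        p2 = partition_factory("BC2", ["CAVGGF", "CAVAAF"], ["CASSNQNTEAFF"])
        table = clonality.assign_clonotypes([p1, p2])
        assert len(table.clones) == 1

    def test_two_beta_multiplets_form_a_single_clone_only_when_included(
            self, partition_factory):
        multi = [partition_factory(f"BC{i}", [], ["CASSAAF", "CASSGGF"])
                 for i in range(2)]
        included = clonality.assign_clonotypes(multi, include_multiplet_beta=True)
        assert len(included.clones) == 1 and included.clones[0].size == 2
        excluded = clonality.assign_clonotypes(multi, include_multiplet_beta=False)
        assert excluded.clones == []

    def test_alpha_only_and_triple_alpha_cells_never_join_clones(
            self, partition_factory):
        parts = [
            partition_factory("BC1", ["CAVAAF"], []),
            partition_factory("BC2", ["CAVAAF", "CAVGGF", "CAVHHF"], ["CASSAAF"]),
            partition_factory("BC3", ["CAVAAF"], ["CASSAAF"]),
        ]
        table = clonality.assign_clonotypes(parts, include_multiplet_beta=True)
        members = {c[2] for clone in table.clones for c in clone.member_cells}
        assert members == {"BC3"}

    def test_cell_conservation(self, small_repertoire):
        from synovitcr import vdj_io
        _, sim = small_repertoire
        parts = vdj_io.build_cell_partitions(vdj_io.records_from_frame(sim.contigs))
        for patient, patient_parts in vdj_io.partitions_by_patient(parts).items():
            table = clonality.assign_clonotypes(patient_parts)
            eligible = [p for p in patient_parts
                        if p.status == vdj_io.PartitionStatus.OK
                        or (p.status == vdj_io.PartitionStatus.MULTIPLET
                            and len(p.beta_chains) >= 2)]
            assert table.n_cells == len(eligible)
            assert sum(table.per_sample_counts.values()) == table.n_cells

    def test_multiple_patients_rejected(self, partition_factory):
        parts = [partition_factory("BC1", [], ["CASSAAF"], patient="P01"),
                 partition_factory("BC2", [], ["CASSAAF"], patient="P02")]
        with pytest.raises(UsageError):
            clonality.assign_clonotypes(parts)


@pytest.fixture(scope="module")
def planted_table():
    # clone 0 planted at 30/3000 vs 2/3000 over a 500-clone background
    background = {i: 6 for i in range(1, 496)}
    counts_a = {0: 30, **background}
    counts_b = {0: 2, **background, 496: 28}
    parts = _partitions_for_counts({"SF": counts_a, "PB": counts_b})
    return clonality.assign_clonotypes(parts)


class TestClonalEnrichment:

    def test_planted_clone_is_flagged_enriched(self, planted_table):
        results = clonality.test_clonal_enrichment(planted_table, ("SF", "PB"))
        flagged = {r.key: r for r in results if r.enriched_in == "SF"}
        planted_key = clonality.clone_key([nt_of(f"AA{_code(0)}")],
                                          [nt_of(f"SS{_code(0)}")])
        assert planted_key in flagged
        assert flagged[planted_key].table[0] == 30

    def test_equal_proportions_never_flagged(self, planted_table):
        results = clonality.test_clonal_enrichment(planted_table, ("SF", "PB"))
        for res in results:
            a, b, c, d = res.table
            if a / (a + b) == c / (c + d):
                assert res.enriched_in is None

    def test_sample_relabeling_swaps_calls(self, planted_table):
        fwd = clonality.test_clonal_enrichment(planted_table, ("SF", "PB"))
        rev = clonality.test_clonal_enrichment(planted_table, ("PB", "SF"))
        fwd_by_key = {r.key: r for r in fwd}
        swap = {"SF": "PB", "PB": "SF", None: None}
        for res in rev:
            other = fwd_by_key[res.key]
            assert res.p_raw == pytest.approx(other.p_raw, rel=1e-12)
            assert res.enriched_in == other.enriched_in  # side names unchanged
        assert ({r.key for r in rev if r.enriched_in}
                == {r.key for r in fwd if r.enriched_in})

    def test_empty_sample_rejected(self, planted_table):
        with pytest.raises(UsageError):
            clonality.test_clonal_enrichment(planted_table, ("SF", "missing"))


class TestClusterAssociation:
    def test_concentrated_cluster_has_maximal_odds_ratio(self):
        universe = {}
        for i in range(40):
            universe[f"e{i}"] = "X"
        for i in range(400):
            universe[f"n{i}"] = "ABCD"[i % 4]
        results = clonality.associate_clusters([f"e{i}" for i in range(40)],
                                               universe)
        best = max(results, key=lambda r: r.odds_ratio)
        assert best.cluster_label == "X"
        assert all(r.p_adj == min(1.0, r.p_raw * len(results)) for r in results)

    def test_cluster_without_cells_not_counted_in_family(self):
        universe = {"e1": "X", "e2": "X", "n1": "Y", "n2": "Y", "n3": "X"}
        results = clonality.associate_clusters({"e1", "e2"}, universe)
        assert len(results) == 2  # only X and Y exist in the universe

    def test_empty_enriched_set_rejected(self):
        with pytest.raises(UsageError):
            clonality.associate_clusters([], {"a": "X", "b": "Y"})

    def test_planted_odds_ratio_recovered_within_band(self, rng):
        """OR 5 planted for one of five clusters over 2000 cells: the estimate
        lands in [3, 8] in at least 90% of 200 seeded replicates."""
        base = np.full(5, 0.2)
        biased = _biased_cluster_probs(base, 0, 5.0)
        hits = 0
        for _ in range(200):
            enr = rng.multinomial(150, biased)
            non = rng.multinomial(1850, base)
            universe, enriched = {}, []
            cell = 0
            for label_idx in range(5):
                for _ in range(enr[label_idx]):
                    universe[cell] = str(label_idx)
                    enriched.append(cell)
                    cell += 1
                for _ in range(non[label_idx]):
                    universe[cell] = str(label_idx)
                    cell += 1
            results = clonality.associate_clusters(enriched, universe)
            estimate = next(r.odds_ratio for r in results if r.cluster_label == "0")
            hits += 3.0 <= estimate <= 8.0
        assert hits / 200 >= 0.90


class TestSubsampling:
    def test_six_samples_at_the_published_depth(self, rng):
        cells = {f"S{i}": [f"S{i}-c{j}" for j in range(7000 + 100 * i)]
                 for i in range(6)}
        subsets = clonality.subsample_equal_depth(cells, target=6867, seed=rng)
        assert all(len(v) == 6867 for v in subsets.values())
        assert sum(len(v) for v in subsets.values()) == 41_202

    def test_target_equal_to_smallest_sample_returns_it_whole(self):
        cells = {"a": list(range(10)), "b": list(range(25))}
        subsets = clonality.subsample_equal_depth(cells, seed=0)
        assert subsets["a"] == list(range(10)) and len(subsets["b"]) == 10

    def test_seed_reproducibility(self):
        cells = {"a": list(range(100)), "b": list(range(120))}
        first = clonality.subsample_equal_depth(cells, target=50, seed=7)
        second = clonality.subsample_equal_depth(cells, target=50, seed=7)
        assert first == second

    def test_explicit_target_larger_than_sample_rejected(self):
        with pytest.raises(UsageError):
            clonality.subsample_equal_depth({"a": [1, 2]}, target=5, seed=0)
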