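"""QC rule engine, MAD bounds, V-J usage weighting and paired panel tests."""
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from synovitcr import summary_stats as ss
from synovitcr.errors import ConfigError, UsageError


def cell(barcode="b", n_genes=1500, n_counts=6000, pct_mito=5.0):
    return ss.CellMetrics(barcode, n_genes, n_counts, pct_mito)


class TestFilterCells:
    @pytest.mark.parametrize(
        "preset,metrics,kept",
        [
            ("droplet_fluid_blood", dict(pct_mito=12.0), False),
            ("droplet_fluid_blood", dict(pct_mito=10.0), True),
            ("droplet_fluid_blood", dict(n_genes=499), False),
            ("droplet_fluid_blood", dict(n_genes=500), True),
            ("droplet_fluid_blood", dict(n_counts=25_001), False),
            ("droplet_tissue", dict(n_genes=150, n_counts=600), False),
            ("droplet_tissue", dict(n_genes=200, n_counts=800), True),
            ("droplet_tissue", dict(n_counts=10_001), False),
        ],
    )
    def test_preset_thresholds_are_strict_inequalities(self, preset, metrics, kept):
        result = ss.filter_cells([cell(**metrics)], preset)
        assert bool(result.kept) is kept

    def test_removed_cells_list_all_firing_rules(self):
        result = ss.filter_cells([cell(pct_mito=15, n_genes=400)],
                                 "droplet_fluid_blood")
        ((_, reasons),) = result.removed
        assert set(reasons) == {"pct_mito>10", "n_genes<500"}

    def test_partition_is_conserved(self, rng):
        cells = [cell(f"b{i}", int(g), int(c), float(m))
                 for i, (g, c, m) in enumerate(zip(
                     rng.integers(100, 5000, 200),
                     rng.integers(1000, 40000, 200),
                     rng.uniform(0, 20, 200)))]
        result = ss.filter_cells(cells, "droplet_fluid_blood")
        assert len(result.kept) + len(result.removed) == len(cells)

    def test_idempotence_on_kept_set(self, rng):
        cells = [cell(f"b{i}", int(g)) for i, g in
                 enumerate(rng.integers(100, 5000, 300))]
        first = ss.filter_cells(cells, "droplet_fluid_blood")
        again = ss.filter_cells(first.kept, "droplet_fluid_blood")
        assert again.removed == []

    def test_rule_firing_is_order_independent(self, rng):
        cells = [cell(f"b{i}", int(g)) for i, g in
                 enumerate(rng.integers(100, 5000, 100))]
        forward = ss.filter_cells(cells, "droplet_fluid_blood")
        backward = ss.filter_cells(cells[::-1], "droplet_fluid_blood")
        assert sorted(c.barcode for c, _ in forward.removed) \
            == sorted(c.barcode for c, _ in backward.removed)

    def test_unknown_metric_and_preset_rejected(self):
        with pytest.raises(ConfigError):
            ss.filter_cells([cell()], [ss.FilterRule("n_reads", ss.RuleKind.GT,
                                                     threshold=1)])
        with pytest.raises(ConfigError):
            ss.filter_cells([cell()], "no_such_preset")

    def test_plate_preset_uses_cohort_mad_for_mitochondria(self):
        cells = [cell(f"b{i}", 3000, 1_000_000, m)
                 for i, m in enumerate([2, 3, 4, 5, 6])]
        outlier = cell("hot", 3000, 1_000_000, 30.0)
        result = ss.filter_cells(cells + [outlier], "plate")
        removed = {c.barcode for c, _ in result.removed}
        assert removed == {"hot"}  # median 4.5, MAD 1.5 -> cutoff 12


class TestMadBounds:
    def test_hand_computed_example(self):
        assert ss.mad_bounds([1, 2, 3, 4, 5], k=1) == (2.0, 4.0)

    def test_constant_vector_collapses(self):
        assert ss.mad_bounds([7.0] * 5, k=3) == (7.0, 7.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(UsageError):
            ss.mad_bounds([1.0], k=1)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40),
           st.floats(0, 10), st.floats(0.01, 100))
    @settings(derandomize=True, max_examples=80)
    def test_scale_equivariance(self, values, k, scale):
        lo, hi = ss.mad_bounds(values, k)
        lo_s, hi_s = ss.mad_bounds([v * scale for v in values], k)
        assert lo_s == pytest.approx(lo * scale, rel=1e-9, abs=1e-6)
        assert hi_s == pytest.approx(hi * scale, rel=1e-9, abs=1e-6)


class TestVJUsage:
    def test_single_patient_single_pairing(self):
        df = pd.DataFrame([("p1", "TRBV28", "TRBJ1-1")] * 5,
                          columns=["patient_id", "v_gene", "j_gene"])
        usage = ss.vj_usage(df)
        assert usage.combined.loc["TRBV28", "TRBJ1-1"] == 1.0

    def test_equal_patient_weighting_worked_example(self):
        rows = ([("p1", "V1", "J1")] * 100
                + [("p2", "V1", "J1")] * 50 + [("p2", "V2", "J2")] * 50)
        usage = ss.vj_usage(pd.DataFrame(rows, columns=["patient_id", "v_gene",
                                                        "j_gene"]))
        assert usage.combined.loc["V1", "J1"] == pytest.approx(0.75)
        assert usage.combined.loc["V2", "J2"] == pytest.approx(0.25)
        assert usage.combined.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_duplicating_one_patients_cells(self):
        rows = ([("p1", "V1", "J1")] * 10
                + [("p2", "V1", "J1")] * 5 + [("p2", "V2", "J2")] * 5)
        df = pd.DataFrame(rows, columns=["patient_id", "v_gene", "j_gene"])
        doubled = pd.concat([df, df[df.patient_id == "p1"]])
        assert ss.vj_usage(df).combined.equals(ss.vj_usage(doubled).combined)


class TestPairedPanel:
    @staticmethod
    def _panel(diffs_by_analyte):
        rows = []
        for analyte, diffs in diffs_by_analyte.items():
            for i, d in enumerate(diffs):
                rows.append((f"S{i}", analyte, 10.0, 10.0 + d))
        return pd.DataFrame(rows, columns=["subject_id", "analyte", "plasma",
                                           "synovial_fluid"])

    def test_t_statistic_matches_closed_form(self):
        diffs = [1.0, 1.2, 0.8, 1.1, 0.9]
        out = ss.paired_panel_test(self._panel({"CXCL10": diffs}))
        d = np.asarray(diffs)
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_expected = 2 * scipy.stats.t.sf(abs(t_expected), df=len(d) - 1)
        assert out.loc[0, "t"] == pytest.approx(t_expected, abs=1e-10)
        assert out.loc[0, "p_raw"] == pytest.approx(p_expected, abs=1e-10)

    def test_zero_variance_yields_nan_not_zero_or_one(self):
        out = ss.paired_panel_test(self._panel({"CXCL9": [0.0] * 5}))
        assert math.isnan(out.loc[0, "t"]) and math.isnan(out.loc[0, "p_raw"])

    def test_bonferroni_multiplies_by_number_of_analytes(self):
        diffs = [1.0, 1.2, 0.8, 1.1, 0.9]
        out = ss.paired_panel_test(self._panel({f"A{i}": diffs for i in range(4)}))
        assert np.allclose(out["p_adj"], np.minimum(1.0, out["p_raw"] * 4))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(UsageError):
            ss.paired_panel_test(self._panel({"CXCL10": [1.0, 2.0]}))
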