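import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptml import (
    DegenerateRegressionError,
    GenePanel,
    WeightTable,
    build_cohort,
    derive_recurrent_panel,
    derive_weights,
    fit_slope,
    read_panel,
    rnd_half_away_from_zero,
    unadjusted_gene_value,
    unadjusted_sample_total,
    write_panel,
)

from conftest import missense


class TestUnadjustedValues:
    def test_min_carrier_load(self, toy_cohort):
        assert unadjusted_gene_value(toy_cohort, "G1") == 10
        assert unadjusted_gene_value(toy_cohort, "G2") == 20

    def test_no_carrier_gives_none(self, toy_cohort):
        assert unadjusted_gene_value(toy_cohort, "NOPE") is None

    def test_single_carrier_with_load_one(self):
        cohort = build_cohort([missense("S1", "G1")])
        assert unadjusted_gene_value(cohort, "G1") == 1

    def test_sample_totals(self, toy_cohort, toy_panel):
        unadjusted = {"G1": 10, "G2": 20}
        totals = {
            s: unadjusted_sample_total(toy_cohort, toy_panel, s, unadjusted)
            for s in ("S0", "S1", "S2")
        }
        assert totals == {"S0": 0, "S1": 10, "S2": 30}

    def test_multiplicity_scales_total(self):
        cohort = build_cohort([missense("S1", "G1"), missense("S1", "G1")])
        panel = GenePanel("p", ("G1",))
        assert unadjusted_sample_total(cohort, panel, "S1", {"G1": 10}) == 20
        assert (
            unadjusted_sample_total(
                cohort, panel, "S1", {"G1": 10}, use_multiplicity=False
            )
            == 10
        )

    def test_unknown_sample_errors(self, toy_cohort, toy_panel):
        with pytest.raises(KeyError):
            unadjusted_sample_total(toy_cohort, toy_panel, "S9", {"G1": 10})


class TestFitSlope:
    def test_three_point_ols(self):
        slope, r2 = fit_slope([0, 10, 20], [0, 10, 30])
        assert slope == pytest.approx(1.5, abs=1e-12)
        assert 0 < r2 <= 1

    @pytest.mark.parametrize("mode", ["ols_intercept", "ols_through_origin"])
    def test_identity_line(self, mode):
        slope, r2 = fit_slope([1, 2, 3, 4], [1, 2, 3, 4], mode)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_response_is_degenerate(self):
        with pytest.raises(DegenerateRegressionError):
            fit_slope([0, 10, 20], [5, 5, 5], "ols_intercept")

    def test_constant_predictor_is_degenerate(self):
        with pytest.raises(DegenerateRegressionError):
            fit_slope([7, 7, 7], [1, 2, 3])

    def test_through_origin_closed_form(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 7.0]
        slope, _ = fit_slope(x, y, "ols_through_origin")
        assert slope == pytest.approx(np.dot(x, y) / np.dot(x, x), abs=1e-12)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(6.6667, 7), (13.3333, 13), (0.5, 1), (0.49, 0), (2.5, 3), (-2.5, -3)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert rnd_half_away_from_zero(value) == expected


class TestDeriveWeights:
    def test_toy_adjusted_values(self, toy_cohort, toy_panel):
        table = derive_weights(toy_cohort, toy_panel)
        assert table.slope == pytest.approx(1.5, abs=1e-12)
        assert table.adjusted == {"G1": 7, "G2": 13}
        assert table.excluded_genes == frozenset()
        assert table.derivation_n_samples == 3

    def test_shared_min_carrier_with_unit_slope(self):
        # one sample of load m carries every panel gene once; a second,
        # heavier sample repeats the genes so the regression slope is 1
        records = [missense("S1", g) for g in ("G1", "G2", "G3")]
        records += [missense("S2", g) for g in ("G1", "G2", "G3")] * 2
        cohort = build_cohort(records)
        panel = GenePanel("p", ("G1", "G2", "G3"))
        table = derive_weights(cohort, panel, mode="ols_through_origin")
        m = cohort.atml["S1"]
        assert set(table.adjusted.values()) == {
            rnd_half_away_from_zero(m / table.slope)
        }

    def test_never_mutated_gene_is_excluded(self, toy_cohort):
        panel = GenePanel("p", ("G1", "G2", "GHOST"))
        table = derive_weights(toy_cohort, panel)
        assert "GHOST" in table.excluded_genes
        assert "GHOST" not in table.adjusted
        assert table.panel_genes == {"G1", "G2", "GHOST"}

    def test_all_genes_excluded_errors(self, toy_cohort):
        with pytest.raises(ValueError, match="carrier"):
            derive_weights(toy_cohort, GenePanel("p", ("GHOST",)))

    def test_deterministic(self, toy_cohort, toy_panel):
        a = derive_weights(toy_cohort, toy_panel)
        b = derive_weights(toy_cohort, toy_panel)
        assert a == b

    def test_monotone_in_min_carrier_load(self):
        # raising the load of G2's only carrier never decreases G2's value
        def make(extra):
            records = [missense("S1", "G1")]
            records += [missense("S1", f"F{i}") for i in range(9)]
            records += [missense("S2", "G2")]
            records += [missense("S2", f"H{i}") for i in range(extra)]
            return build_cohort(records)

        values = [unadjusted_gene_value(make(extra), "G2") for extra in (5, 10, 20)]
        assert values == sorted(values)

    def test_scale_equivariance_through_origin(self, toy_panel):
        """Scaling every load by c scales both regression axes by c, so the
        through-origin slope is unchanged and the adjusted values scale by c
        (up to rounding) — predicted loads track the load scale."""

        def cohort_scaled(c):
            records = [missense("S1", "G1")]
            records += [missense("S1", f"F{i:03d}") for i in range(10 * c - 1)]
            records += [missense("S2", "G1"), missense("S2", "G2")]
            records += [missense("S2", f"F{i:03d}") for i in range(20 * c - 2)]
            return build_cohort(records, sample_universe={"S0", "S1", "S2"})

        base = derive_weights(cohort_scaled(1), toy_panel, mode="ols_through_origin")
        scaled = derive_weights(cohort_scaled(3), toy_panel, mode="ols_through_origin")
        assert scaled.slope == pytest.approx(base.slope, abs=1e-12)
        for gene in ("G1", "G2"):
            assert scaled.unadjusted[gene] == 3 * base.unadjusted[gene]
            assert abs(scaled.adjusted[gene] - 3 * base.adjusted[gene]) <= 2


class TestRecurrentPanel:
    def test_top_k_by_carriers(self):
        records = (
            [missense(s, "G1") for s in "ABC"]
            + [missense(s, "G2") for s in "AB"]
            + [missense("A", "G3")]
        )
        cohort = build_cohort(records)
        assert derive_recurrent_panel(cohort, 2).genes == ("G1", "G2")

    def test_k_equals_all_mutated_genes(self):
        cohort = build_cohort([missense("A", "G1"), missense("B", "G2")])
        assert set(derive_recurrent_panel(cohort, 2).genes) == {"G1", "G2"}

    def test_tie_break_total_count_then_symbol(self):
        # G2 and G3 tie on carriers; G3 has more total mutations; G1/G2 then
        # tie fully and resolve lexicographically
        records = [
            missense("A", "G1"),
            missense("A", "G2"),
            missense("A", "G3"),
            missense("A", "G3"),
        ]
        cohort = build_cohort(records)
        panel = derive_recurrent_panel(cohort, 3)
        assert panel.genes == ("G3", "G1", "G2")
        assert derive_recurrent_panel(cohort, 3).genes == panel.genes

    def test_k_too_large_errors(self, toy_cohort):
        with pytest.raises(ValueError):
            derive_recurrent_panel(toy_cohort, 10_000)


class TestSerialization:
    def test_weight_table_round_trip_bit_exact(self, toy_cohort, toy_panel, tmp_path):
        panel = GenePanel("p", ("G1", "G2", "GHOST"))
        table = derive_weights(toy_cohort, panel, cancer_label="toy")
        path = tmp_path / "weights.tsv"
        table.to_tsv(path)
        reread = WeightTable.from_tsv(path)
        assert reread == table
        assert reread.slope == table.slope  # bit-exact float

    def test_panel_file_round_trip_and_comments(self, tmp_path):
        path = tmp_path / "panel.txt"
        path.write_text("# my panel\nbraf\nTP53  # tumor suppressor\n\negfr\n")
        panel = read_panel(path)
        assert panel.genes == ("BRAF", "TP53", "EGFR")
        out = tmp_path / "out.txt"
        write_panel(panel, out)
        assert read_panel(out).genes == panel.genes

    def test_duplicate_panel_symbols_rejected(self, tmp_path):
        path = tmp_path / "panel.txt"
        path.write_text("BRAF\nbraf\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_panel(path)
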