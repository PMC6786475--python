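"""Fixation summary, dN/dS site counting, accumulation and mutator tests."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_record, table1_records

from podevol.evo_summary import (
    accumulation_regression,
    cds_site_counts,
    dnds,
    is_transition,
    mutator_test,
    new_fixation_counts,
    passages_per_fixation,
    round_half_up,
    summarize_fixations,
)
from podevol.genome_model import GeneModel, Genome


class TestSummarizeFixations:
    def test_published_style_shares(self):
        s = summarize_fixations(table1_records())
        assert s.total_fixations == 148
        assert s.total_snvs == 125
        assert s.per_lineage_snvs == {"A": 85, "B": 40}
        assert s.share_percent("missense") == 35.1
        assert s.share_percent("nonsense") == 7.4
        assert s.share_percent("frameshift") == 8.8

    def test_transition_shares_whole_percent(self):
        s = summarize_fixations(table1_records())
        assert s.transition_share_percent("A") == 73   # 62/85
        assert s.transition_share_percent("B") == 53   # 21/40, ties up
        assert s.per_lineage_transitions == {"A": 62, "B": 21}
        assert s.per_lineage_transversions == {"A": 23, "B": 19}

    def test_counts_conserved_and_percentages_recompute(self):
        s = summarize_fixations(table1_records())
        for lin in ("A", "B"):
            assert (s.per_lineage_transitions[lin]
                    + s.per_lineage_transversions[lin]
                    == s.per_lineage_snvs[lin])
            assert (sum(s.per_lineage_effects[lin].values())
                    == s.per_lineage_totals[lin])
        for eff in ("missense", "nonsense", "frameshift"):
            expected = round_half_up(100 * s.effect_total(eff) / 148, 1)
            assert s.share_percent(eff) == expected

    def test_single_transition(self):
        s = summarize_fixations([make_record("A1", "missense")])
        assert s.transition_share_percent("A") == 100

    def test_empty_input_percentages_undefined(self):
        s = summarize_fixations([])
        assert s.total_fixations == 0
        assert s.share_percent("missense") is None

    @pytest.mark.parametrize("ref,alt,ts", [
        ("A", "G", True), ("G", "A", True), ("C", "T", True), ("T", "C", True),
        ("A", "C", False), ("A", "T", False), ("G", "C", False),
    ])
    def test_transition_definition(self, ref, alt, ts):
        assert is_transition(ref, alt) is ts


class TestDnds:
    def test_phe_codon_site_weights(self):
        # TTT: of the nine single-base changes only TTT->TTC is silent
        genome = Genome({"c": "ATGTTTTAA"})
        gene = GeneModel("g", "c", "+", ((0, 9),))
        sites_n, sites_s = cds_site_counts([gene], genome)
        # ATG contributes 0 synonymous sites, TAA->TGA/TAG are stop-to-stop
        expected_syn = 0 + 1 / 3 + 2 / 3
        assert sites_s == pytest.approx(expected_syn)
        assert sites_n + sites_s == pytest.approx(9)

    def test_sites_sum_to_cds_length(self, experiment):
        complete = [g for g in experiment.gene_models if g.complete]
        subset = complete[:25]
        sites_n, sites_s = cds_site_counts(subset, experiment.genome)
        assert sites_n + sites_s == pytest.approx(
            sum(g.cds_length for g in subset)
        )

    def test_sites_sum_with_tstv_weighting(self, experiment):
        complete = [g for g in experiment.gene_models if g.complete][:10]
        sites_n, sites_s = cds_site_counts(complete, experiment.genome,
                                           tstv=2.0)
        assert sites_n + sites_s == pytest.approx(
            sum(g.cds_length for g in complete)
        )

    def test_all_synonymous_gives_zero(self, experiment):
        records = [make_record("A1", "synonymous", position=i * 10)
                   for i in range(5)]
        complete = [g for g in experiment.gene_models if g.complete][:5]
        res = dnds(records, complete, experiment.genome)
        assert res.ratio == 0.0

    def test_no_synonymous_flagged_infinite(self, experiment):
        records = [make_record("A1", "missense", position=i * 10)
                   for i in range(5)]
        complete = [g for g in experiment.gene_models if g.complete][:5]
        res = dnds(records, complete, experiment.genome)
        assert res.infinite

    def test_neutral_simulation_near_one(self, experiment, effect_lookup):
        """Uniform coding SNVs (n=1000) must give dN/dS in [0.9, 1.1]."""
        from helpers import neutral_dnds_ratio

        ratio = neutral_dnds_ratio(experiment, effect_lookup)
        assert 0.9 <= ratio <= 1.1


class TestAccumulationRegression:
    TPS = (75, 130, 200, 268)

    def _counts_from_rates(self, rate_fn):
        bounds = [0, *self.TPS]
        counts = {}
        for pop in ("A1", "A2", "B1"):
            counts[pop] = {
                hi: rate_fn((lo + hi) / 2) * (hi - lo)
                for lo, hi in zip(bounds, bounds[1:])
            }
        return counts

    def test_constant_rate_zero_slope(self):
        fit = accumulation_regression(self._counts_from_rates(lambda t: 0.1),
                                      self.TPS)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_recovery(self):
        fit = accumulation_regression(
            self._counts_from_rates(lambda t: 0.2 - 0.0005 * t), self.TPS
        )
        assert fit.slope == pytest.approx(-0.0005, abs=1e-12)
        assert fit.intercept == pytest.approx(0.2, abs=1e-10)
        assert fit.slope_p < 1e-10

    def test_single_interval_undefined(self):
        with pytest.raises(ValueError):
            accumulation_regression({"A1": {75: 3}}, (75,))


class TestPassagesPerFixation:
    def test_published_scale(self):
        raw, rounded = passages_per_fixation(8, 268, 148)
        assert raw == pytest.approx(14.486, abs=1e-3)
        assert rounded == 14

    def test_simple_case(self):
        assert passages_per_fixation(2, 50, 10) == (10.0, 10)

    def test_zero_fixations_undefined(self):
        with pytest.raises(ValueError):
            passages_per_fixation(1, 100, 0)


class TestMutatorTest:
    TPS = (75, 130, 200, 268)
    POPS = ("A1", "A2", "A3", "A4", "A5", "B1", "B2", "B3")

    def _poisson_counts(self, rng, rates=None):
        rates = rates or {p: 4.6 for p in self.POPS}
        return {
            p: {t: int(rng.poisson(rates[p])) for t in self.TPS}
            for p in self.POPS
        }

    def test_identical_counts_degenerate_convention(self):
        counts = {p: {t: 4 for t in self.TPS} for p in self.POPS}
        res = mutator_test(counts)
        assert res.lineage_p == 1.0 and res.population_p == 1.0

    def test_strong_mutator_detected(self):
        rng = np.random.default_rng(7)
        rates = {p: 4.6 for p in self.POPS}
        rates["A3"] = 46.0
        res = mutator_test(self._poisson_counts(rng, rates))
        assert res.population_p < 0.01

    def test_type_one_error_calibration(self):
        """Null rejection rate of the lineage factor near the nominal 5%."""
        rng = np.random.default_rng(2718)
        rejections = 0
        for _ in range(100):
            res = mutator_test(self._poisson_counts(rng))
            if res.lineage_p < 0.05:
                rejections += 1
        assert 2 <= rejections <= 9


class TestNewFixationCounts:
    def test_first_seen_binning_and_time_unknown_exclusion(self):
        records = [
            make_record("A1", "missense", position=10,
                        first_seen_timepoint=75),
            make_record("A1", "missense", position=20,
                        first_seen_timepoint=75),
            make_record("A1", "synonymous", position=30,
                        first_seen_timepoint=268),
            make_record("B1", "missense", position=40,
                        first_seen_timepoint=130),
            make_record("B1", "missense", position=50,
                        validation_status="time_unknown"),
        ]
        counts = new_fixation_counts(records, (75, 130, 200, 268),
                                     populations=("A1", "B1", "B2"))
        assert counts["A1"] == {75: 2, 130: 0, 200: 0, 268: 1}
        assert counts["B1"] == {75: 0, 130: 1, 200: 0, 268: 0}
        assert counts["B2"] == {75: 0, 130: 0, 200: 0, 268: 0}


@given(st.floats(0, 1000), st.integers(0, 3))
@settings(max_examples=50, deadline=None)
def test_round_half_up_matches_decimal(x, digits):
    import decimal

    expected = float(
        decimal.Decimal(str(x)).quantize(
            decimal.Decimal(1).scaleb(-digits), rounding=decimal.ROUND_HALF_UP
        )
    )
    assert round_half_up(x, digits) == pytest.approx(expected, abs=10 ** -(digits + 6))
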