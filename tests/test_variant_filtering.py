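"""Exclusion rules: boundary behaviour, audit trail and reconciliation."""
import pytest

from helpers import stub_call

from podevol.genome_model import MaskInterval
from podevol.variant_filtering import (
    FilterConfig,
    FounderEvidence,
    apply_adjacency_filter,
    apply_filters,
    apply_founder_filter,
    apply_mask_filter,
    apply_multipopulation_filter,
    apply_quality_filter,
    reconcile_timepoints,
)

CFG = FilterConfig()


class TestQualityFilter:
    @pytest.mark.parametrize("coverage,alt,freq,kept", [
        (10, 8, 0.80, True),    # both thresholds inclusive
        (9, 9, 1.0, False),     # low coverage trumps perfect frequency
        (100, 79, 0.79, False),
        (40, 40, 1.0, True),
    ])
    def test_boundaries(self, coverage, alt, freq, kept):
        call = stub_call(coverage=coverage, alt_reads=alt, frequency=freq)
        survivors, removed = apply_quality_filter([call], CFG)
        assert (len(survivors) == 1) is kept


class TestFounderFilter:
    def _founder(self, alt_reads, coverage=40):
        f = FounderEvidence()
        f.set("P", "c1", 0, "G", coverage, alt_reads)
        return f

    def test_two_founder_reads_remove(self):
        _, removed = apply_founder_filter([stub_call()], self._founder(2), CFG)
        assert len(removed) == 1

    def test_one_founder_read_keeps(self):
        kept, _ = apply_founder_filter([stub_call()], self._founder(1), CFG)
        assert len(kept) == 1

    def test_uncovered_founder_site_kept_by_this_rule(self):
        kept, _ = apply_founder_filter(
            [stub_call()], self._founder(0, coverage=0), CFG
        )
        assert len(kept) == 1


class TestMultiPopulationFilter:
    def _calls(self):
        return [
            stub_call(sample="A1_p268", population="A1"),
            stub_call(sample="A2_p268", population="A2"),
        ]

    def test_shared_site_with_zero_founder_coverage_removed(self):
        founder = FounderEvidence()
        founder.set("A", "c1", 0, "G", 0, 0)
        kept, removed = apply_multipopulation_filter(self._calls(), founder, CFG)
        assert not kept and len(removed) == 2

    def test_shared_site_with_covered_founder_kept(self):
        # genuine parallel fixation: founder covered, no alt reads
        founder = FounderEvidence(default_coverage=30)
        kept, removed = apply_multipopulation_filter(self._calls(), founder, CFG)
        assert len(kept) == 2 and not removed

    def test_single_population_kept(self):
        founder = FounderEvidence()
        founder.set("A", "c1", 0, "G", 0, 0)
        kept, _ = apply_multipopulation_filter(self._calls()[:1], founder, CFG)
        assert len(kept) == 1


class TestMaskFilter:
    MASKS = [MaskInterval("c1", 100, 200)]

    @pytest.mark.parametrize("pos,kept", [
        (209, False),   # 10 bp past the mask end: inclusive flank (209 < 210)
        (210, True),    # 11 bp past: outside
        (90, False),    # 10 bp before the start
        (89, True),
        (150, False),   # inside
    ])
    def test_indel_flanks(self, pos, kept):
        call = stub_call(position=pos, ref="T", alt="")
        survivors, _ = apply_mask_filter([call], self.MASKS, CFG)
        assert (len(survivors) == 1) is kept

    def test_snv_inside_mask_kept(self):
        call = stub_call(position=150)
        survivors, _ = apply_mask_filter([call], self.MASKS, CFG)
        assert len(survivors) == 1


class TestAdjacencyFilter:
    def test_adjacent_pair_removed(self):
        calls = [stub_call(position=100), stub_call(position=101, ref="C", alt="T")]
        kept, removed = apply_adjacency_filter(calls, CFG)
        assert not kept and len(removed) == 2

    def test_distance_two_kept(self):
        calls = [stub_call(position=100), stub_call(position=102, ref="C", alt="T")]
        kept, _ = apply_adjacency_filter(calls, CFG)
        assert len(kept) == 2

    def test_different_populations_kept(self):
        calls = [
            stub_call(position=100, sample="A1_p268", population="A1"),
            stub_call(position=101, ref="C", alt="T", sample="A2_p268",
                      population="A2"),
        ]
        kept, _ = apply_adjacency_filter(calls, CFG)
        assert len(kept) == 2

    def test_indels_not_affected(self):
        calls = [stub_call(position=100, ref="T", alt=""), stub_call(position=101)]
        kept, _ = apply_adjacency_filter(calls, CFG)
        assert len(kept) == 2


class TestCompositeFilter:
    def test_subset_and_idempotence(self, experiment):
        report = apply_filters(
            experiment.calls, experiment.founder, experiment.masks
        )
        assert report.n_input == len(experiment.calls)
        # applying the composite again changes nothing
        report2 = apply_filters(
            report.survivors, experiment.founder, experiment.masks
        )
        assert report2.survivors == report.survivors
        assert sum(report2.removal_counts.values()) == 0

    def test_each_artifact_removed_by_designated_rule(self, experiment):
        report = apply_filters(
            experiment.calls, experiment.founder, experiment.masks
        )
        removed_by = {}
        for rule, calls in report.removed.items():
            for c in calls:
                removed_by[(c.population_id, c.contig, c.position,
                            c.ref, c.alt)] = rule
        assert experiment.truth.artifacts, "fixture must plant artifacts"
        for artifact in experiment.truth.artifacts:
            assert removed_by.get(artifact.key()) == artifact.removing_filter, \
                f"{artifact.key()} not removed by {artifact.removing_filter}"

    def test_all_true_fixations_survive(self, experiment):
        report = apply_filters(
            experiment.calls, experiment.founder, experiment.masks
        )
        surviving = {
            (c.population_id, c.contig, c.position, c.ref, c.alt)
            for c in report.survivors
        }
        truth = experiment.truth.fixation_keys()
        assert truth <= surviving
        assert surviving == truth  # and nothing else survives


class TestReconcileTimepoints:
    TPS = (75, 130, 200, 268)

    def test_confirmed_once_imputed_monotone(self):
        validation = {"m": {75: False, 130: True, 200: None, 268: None}}
        presence = {"m": {75: False, 130: True, 200: True, 268: True}}
        (rec,), warnings = reconcile_timepoints(presence, validation, self.TPS)
        assert rec.validation_status == "verified"
        assert rec.first_seen_timepoint == 130
        assert rec.imputed_presence == (130, 200, 268)
        assert not warnings

    def test_confirmed_nowhere_unverifiable(self):
        validation = {"m": {t: None for t in self.TPS}}
        (rec,), _ = reconcile_timepoints({}, validation, self.TPS)
        assert rec.validation_status == "unverifiable"

    def test_loss_after_appearance_warns(self):
        validation = {"m": {75: True, 130: None, 200: None, 268: True}}
        presence = {"m": {75: True, 130: False, 200: False, 268: True}}
        (rec,), warnings = reconcile_timepoints(presence, validation, self.TPS)
        assert rec.validation_status == "verified"
        assert len(warnings) == 1 and "non-monotone" in warnings[0]

    def test_final_only_with_failed_assays_is_time_unknown(self):
        validation = {"m": {75: None, 130: None, 200: None, 268: True}}
        (rec,), _ = reconcile_timepoints({}, validation, self.TPS)
        assert rec.validation_status == "time_unknown"
        assert rec.first_seen_timepoint is None
        assert rec.imputed_presence == (268,)

    def test_final_only_with_negative_assays_is_late_fixation(self):
        validation = {"m": {75: False, 130: False, 200: False, 268: True}}
        (rec,), _ = reconcile_timepoints({}, validation, self.TPS)
        assert rec.validation_status == "verified"
        assert rec.first_seen_timepoint == 268
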