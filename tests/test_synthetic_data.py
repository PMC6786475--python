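"""Synthetic experiment generator: determinism, truth-ledger consistency,
monotone presence and statistical scale."""
import numpy as np
import pytest

from podevol.genome_model import evaluate_completeness, read_genome
from podevol.synthetic_data import (
    ConfigError,
    ExperimentConfig,
    ParallelTarget,
    generate_experiment,
    generate_genome_and_annotation,
    simulate_experiment,
    write_experiment,
)

SMALL = dict(n_contigs=1, contig_length=120_000, gene_density=0.15,
             mean_cds_length=600, n_masks_per_contig=4)


class TestGenomeGeneration:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = ExperimentConfig(seed=5, **SMALL)
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        for out in (out_a, out_b):
            exp = generate_experiment(cfg)
            write_experiment(exp, out, vcf=False)
        for name in ("founder.fasta", "genes.gff3", "mask.bed",
                     "variants.tsv", "truth.tsv", "orthologs.tsv"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_zero_density_emits_genome_without_genes(self):
        cfg = ExperimentConfig(seed=2, n_contigs=1, contig_length=50_000,
                               gene_density=0.0, n_masks_per_contig=2,
                               parallel_targets=())
        genome, genes, masks = generate_genome_and_annotation(cfg)
        assert genome.total_length == 50_000
        assert genes == [] and masks

    def test_requested_gene_count_realized(self):
        # ten 300 bp genes on a 10 kb contig
        cfg = ExperimentConfig(seed=3, n_contigs=1, contig_length=10_000,
                               gene_density=0.30, mean_cds_length=300,
                               intron_probability=0.0,
                               incomplete_gene_fraction=0.0,
                               n_masks_per_contig=0, parallel_targets=())
        genome, genes, _ = generate_genome_and_annotation(cfg)
        assert len(genes) == 10
        assert all(evaluate_completeness(g, genome) for g in genes)

    def test_infeasible_density_raises(self):
        cfg = ExperimentConfig(seed=0, n_contigs=1, contig_length=5_000,
                               gene_density=0.99, n_masks_per_contig=0)
        with pytest.raises(ConfigError):
            generate_genome_and_annotation(cfg)

    def test_masks_do_not_touch_genes_or_edges(self):
        cfg = ExperimentConfig(seed=4, **SMALL)
        genome, genes, masks = generate_genome_and_annotation(cfg)
        spans = [(g.contig, *g.span) for g in genes]
        for m in masks:
            assert m.start >= 20
            assert m.end <= genome.lengths()[m.contig] - 20
            for contig, s, e in spans:
                if contig == m.contig:
                    assert m.end <= s or m.start >= e

    def test_completeness_fraction_respected(self):
        cfg = ExperimentConfig(seed=6, incomplete_gene_fraction=0.3, **SMALL)
        genome, genes, _ = generate_genome_and_annotation(cfg)
        incomplete = [g for g in genes if not g.complete]
        assert incomplete
        for g in genes:
            assert evaluate_completeness(g, genome) == g.complete


class TestSimulation:
    def test_zero_rates_empty_tables(self):
        cfg = ExperimentConfig(
            seed=1, per_passage_fixation_rate=0.0, parallel_targets=(),
            n_low_coverage_artifacts=0, n_founder_supported_artifacts=0,
            n_multipopulation_artifacts=0, n_adjacent_pair_artifacts=0,
            n_masked_indel_artifacts=0, **SMALL,
        )
        exp = generate_experiment(cfg)
        assert exp.calls == []
        assert exp.truth.fixations == [] and exp.truth.artifacts == []

    def test_presence_monotone_by_construction(self, experiment):
        presence = experiment.ngs_presence()
        tps = experiment.config.timepoints
        for key, row in presence.items():
            if key in {a.key() for a in experiment.truth.artifacts}:
                continue
            seen = [t for t in tps if row[t]]
            assert seen, f"{key} never present"
            first = seen[0]
            assert all(row[t] for t in tps if t >= first), \
                f"{key} lost after appearing"

    def test_planted_fixations_fully_evidenced(self, experiment):
        cfg = experiment.config
        artifact_keys = {a.key() for a in experiment.truth.artifacts}
        for c in experiment.calls:
            key = (c.population_id, c.contig, c.position, c.ref, c.alt)
            if key in artifact_keys:
                continue
            assert c.coverage >= cfg.mean_depth // 2
            assert c.frequency >= 0.90

    def test_six_frameshifts_planted_in_parallel_gene(self, experiment):
        target = experiment.config.parallel_targets[0]
        assert target.effect == "frameshift"
        gene_id = sorted(
            {f.gene_id for f in experiment.truth.fixations
             if f.intended_effect == "frameshift"
             and len([x for x in experiment.truth.fixations
                      if x.gene_id == f.gene_id]) >= len(target.populations)}
        )[0]
        hits = [f for f in experiment.truth.fixations if f.gene_id == gene_id
                and f.intended_effect == "frameshift"]
        assert len(hits) >= len(target.populations)
        assert len({f.population for f in hits}) >= len(target.populations)

    def test_artifacts_name_exactly_one_filter(self, experiment):
        allowed = {"quality", "founder", "multi_population", "mask",
                   "adjacency"}
        assert experiment.truth.artifacts
        for a in experiment.truth.artifacts:
            assert a.removing_filter in allowed

    def test_fixation_count_scales_with_rate(self):
        cfg = ExperimentConfig(seed=11, parallel_targets=(), **SMALL)
        totals = []
        for seed in range(3):
            exp = generate_experiment(
                ExperimentConfig(seed=seed, parallel_targets=(), **SMALL)
            )
            totals.append(len(exp.truth.fixations))
        expected = (cfg.per_passage_fixation_rate * max(cfg.timepoints)
                    * len(cfg.populations))
        mean = np.mean(totals)
        # Poisson with mean ~125 per experiment; 3 experiments
        assert abs(mean - expected) < 4 * np.sqrt(expected / 3)

    def test_unverifiable_and_time_unknown_planting(self):
        cfg = ExperimentConfig(seed=9, n_unverifiable=5, n_time_unknown=3,
                               parallel_targets=(), **SMALL)
        exp = generate_experiment(cfg)
        labels = [f.validation for f in exp.truth.fixations]
        assert labels.count("unverifiable") == 5
        assert labels.count("time_unknown") == 3
        for f in exp.truth.fixations:
            row = exp.validation[f.key()]
            if f.validation == "unverifiable":
                assert all(v is None for v in row.values())
            elif f.validation == "time_unknown":
                assert row[max(cfg.timepoints)] is True
                assert all(row[t] is None for t in cfg.timepoints[:-1])

    def test_written_genome_reloads(self, tmp_path, experiment):
        paths = write_experiment(experiment, tmp_path, vcf=False)
        genome = read_genome(paths["genome"])
        assert genome.contigs == experiment.genome.contigs


class TestParallelTargetValidation:
    def test_unknown_effect_rejected(self):
        with pytest.raises(ConfigError):
            ParallelTarget(0, "synonymous", ("A1",))

    def test_unknown_population_rejected(self):
        cfg = ExperimentConfig(
            seed=1, parallel_targets=(
                ParallelTarget(0, "missense", ("Z9",)),
            ), **SMALL,
        )
        genome, genes, masks = generate_genome_and_annotation(cfg)
        with pytest.raises(ConfigError):
            simulate_experiment(genome, genes, masks, cfg)

    def test_bad_rate_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentConfig(gene_density=1.5)
        with pytest.raises(ConfigError):
            ExperimentConfig(timepoints=(130, 75))
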