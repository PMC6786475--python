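import pytest

from podevol.effect_annotation import EffectLookup
from podevol.permutation_null import build_context_index
from podevol.synthetic_data import ExperimentConfig, generate_experiment


@pytest.fixture(scope="session")
def experiment():
    """One full-size synthetic experiment shared by the whole session."""
    return generate_experiment(ExperimentConfig(seed=1))


@pytest.fixture(scope="session")
def effect_lookup(experiment):
    return EffectLookup(experiment.genome, experiment.gene_models)


@pytest.fixture(scope="session")
def context_index(experiment):
    return build_context_index(experiment.genome)


@pytest.fixture(scope="session")
def tiny_annotated_genome():
    """A ~2 kb genome with a handful of genes, for brute-force oracles."""
    from podevol.synthetic_data import generate_genome_and_annotation

    cfg = ExperimentConfig(
        seed=7, n_contigs=1, contig_length=2000, gene_density=0.45,
        mean_cds_length=300, intron_probability=0.4, intron_length=30,
        incomplete_gene_fraction=0.2, n_masks_per_contig=0,
    )
    return generate_genome_and_annotation(cfg)
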