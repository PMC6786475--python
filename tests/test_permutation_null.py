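"""Permutation engine: context index, placement fidelity, exact-enumeration
agreement and the parallel-gene statistic."""
import itertools

import numpy as np
import pytest

from podevol.effect_annotation import EffectLookup, _BASE_INDEX, CODE_MISSENSE
from podevol.genome_model import GeneModel, Genome
from podevol.permutation_null import (
    ObservedSnv,
    PermutationConfig,
    PermutationResult,
    build_context_index,
    null_effect_counts,
    null_parallel_genes,
    observed_parallel_gene_count,
    permute_once,
)


class TestContextIndex:
    def test_homopolymer(self):
        idx = build_context_index(Genome({"c": "AAAA"}))
        assert idx.positions["AAA"].tolist() == [1, 2]

    def test_two_kmers(self):
        idx = build_context_index(Genome({"c": "ACGT"}))
        assert idx.positions["ACG"].tolist() == [1]
        assert idx.positions["CGT"].tolist() == [2]

    def test_n_windows_excluded(self):
        idx = build_context_index(Genome({"c": "ANGTT"}))
        # windows containing N are ineligible; only GTT at position 3 remains
        assert idx.n_eligible() == 1
        assert idx.positions["GTT"].tolist() == [3]

    def test_counts_cover_all_eligible_positions(self, experiment,
                                                 context_index):
        total = sum(v.size for v in context_index.positions.values())
        expected = sum(len(s) - 2 for s in experiment.genome.contigs.values())
        assert total == context_index.n_eligible() == expected

    def test_key_matches_position_context(self, experiment, context_index):
        offsets = {}
        off = 0
        for cid, seq in experiment.genome.contigs.items():
            offsets[cid] = (off, off + len(seq), seq)
            off += len(seq)
        rng = np.random.default_rng(3)
        for kmer in list(context_index.positions)[:10]:
            pool = context_index.positions[kmer]
            for g in rng.choice(pool, size=min(20, pool.size), replace=False):
                for lo, hi, seq in offsets.values():
                    if lo <= g < hi:
                        assert seq[g - lo - 1 : g - lo + 2] == kmer
                        break


class TestPlacement:
    def test_conservation_and_context_fidelity(self, experiment, context_index):
        observed = [
            ObservedSnv(ctx, alt)
            for ctx, alt in [("ACG", "T"), ("TTT", "C"), ("GGA", "A"),
                             (None, "G")] * 10
        ]
        rng = np.random.default_rng(11)
        for _ in range(25):
            placed = permute_once(observed, context_index, rng)
            assert placed.size == len(observed)
            for snv, pos in zip(observed, placed):
                if snv.context is None:
                    assert pos in context_index.all_eligible
                else:
                    assert pos in context_index.positions[snv.context]

    def test_degenerate_single_position_context(self):
        genome = Genome({"c": "TTACGTT"})  # "ACG" occurs once, centre pos 3
        idx = build_context_index(genome)
        assert idx.positions["ACG"].size == 1
        rng = np.random.default_rng(0)
        for _ in range(10):
            (pos,) = permute_once([ObservedSnv("ACG", "T")], idx, rng)
            assert pos == 3

    def test_unknown_context_falls_back_to_uniform_pool(self):
        idx = build_context_index(Genome({"c": "AAAAAA"}))
        rng = np.random.default_rng(0)
        (pos,) = permute_once([ObservedSnv("CCC", "T")], idx, rng)
        assert pos in idx.all_eligible

    def test_no_context_mode_uniform(self, context_index):
        rng = np.random.default_rng(1)
        placed = permute_once(
            [ObservedSnv("ACG", "T")] * 50, context_index, rng,
            context_matched=False,
        )
        # uniform placement is not confined to the 'ACG' pool
        assert not np.isin(placed, context_index.positions["ACG"]).all()


def _toy_gene_genome():
    """A 38 bp genome holding one complete 6-codon gene."""
    gene_seq = "ATGAAACCCGGGTTTTAA"
    genome = Genome({"c": "ACGTACGTAC" + gene_seq + "GTACGTACGT"})
    gene = GeneModel("g1", "c", "+", ((10, 28),))
    return genome, [gene]


class TestExactEnumeration:
    """Monte Carlo tails match exhaustive enumeration on a tiny genome."""

    def test_tail_probabilities_within_three_se(self):
        genome, genes = _toy_gene_genome()
        lookup = EffectLookup(genome, genes)
        index = build_context_index(genome)
        observed = [ObservedSnv("AAA", "G"), ObservedSnv("CGT", "A")]
        pools = [index.eligible(s.context) for s in observed]
        assert 1 < pools[0].size * pools[1].size <= 100
        # exact null of the missense count
        alt_idx = [_BASE_INDEX[s.alt] for s in observed]
        exact_counts = {}
        for p1, p2 in itertools.product(pools[0], pools[1]):
            stat = int(lookup.effect[p1, alt_idx[0]] == CODE_MISSENSE) + \
                   int(lookup.effect[p2, alt_idx[1]] == CODE_MISSENSE)
            exact_counts[stat] = exact_counts.get(stat, 0) + 1
        n_combos = pools[0].size * pools[1].size
        n_reps = 50_000
        results = null_effect_counts(
            genome, lookup, index, observed,
            {"nonsense": 0, "missense": 1},
            PermutationConfig(n_reps=n_reps, seed=2024),
        )
        hist = results["missense"].null_histogram
        assert sum(hist.values()) == n_reps
        for t in range(0, 3):
            exact_tail = sum(v for k, v in exact_counts.items() if k >= t) \
                / n_combos
            mc_tail = sum(v for k, v in hist.items() if k >= t) / n_reps
            se = np.sqrt(max(exact_tail * (1 - exact_tail), 1e-12) / n_reps)
            assert abs(mc_tail - exact_tail) <= 3 * se + 1e-12, \
                f"tail at {t}: exact {exact_tail}, MC {mc_tail}"

    def test_seed_reproducibility(self):
        genome, genes = _toy_gene_genome()
        lookup = EffectLookup(genome, genes)
        index = build_context_index(genome)
        # the TTT pool holds one missense and one synonymous site, so the
        # null genuinely varies between replicates
        observed = [ObservedSnv("TTT", "C"), ObservedSnv("CGT", "A")]
        kwargs = dict(observed_snvs=observed,
                      observed_counts={"nonsense": 0, "missense": 1})
        a = null_effect_counts(genome, lookup, index,
                               config=PermutationConfig(n_reps=3000, seed=5),
                               **kwargs)
        b = null_effect_counts(genome, lookup, index,
                               config=PermutationConfig(n_reps=3000, seed=5),
                               **kwargs)
        c = null_effect_counts(genome, lookup, index,
                               config=PermutationConfig(n_reps=3000, seed=6),
                               **kwargs)
        assert a["missense"].null_histogram == b["missense"].null_histogram
        assert a["missense"].null_histogram != c["missense"].null_histogram


class TestPermutationResult:
    def test_p_monotone_in_observed(self):
        from collections import Counter

        hist = Counter({0: 50, 1: 30, 2: 15, 3: 5})
        ps = [
            PermutationResult("s", obs, hist, n_reps=100).p_value
            for obs in range(5)
        ]
        assert ps == sorted(ps, reverse=True)
        assert ps[0] == 1.0 and ps[4] == 0.0

    def test_add_one_estimator(self):
        from collections import Counter

        hist = Counter({0: 100})
        r = PermutationResult("s", 5, hist, n_reps=100, add_one=True)
        assert r.p_value == pytest.approx(1 / 101)


class TestParallelGenes:
    def test_degenerate_contexts_force_one_gene(self):
        genome, genes = _toy_gene_genome()
        lookup = EffectLookup(genome, genes)
        index = build_context_index(genome)
        # both contexts occur only inside the gene and both changes are
        # protein-altering there
        observed = [ObservedSnv("AAA", "G"), ObservedSnv("CCC", "A")]
        for snv in observed:
            assert index.positions[snv.context].size == 1
        result = null_parallel_genes(
            [lookup], [index], [observed], observed_statistic=1,
            config=PermutationConfig(n_reps=500, seed=1),
        )
        assert result.null_histogram == {1: 500}
        assert result.p_value == 1.0

    def test_zero_observed_snvs(self, experiment, effect_lookup, context_index):
        result = null_parallel_genes(
            [effect_lookup], [context_index], [[]], observed_statistic=0,
            config=PermutationConfig(n_reps=50, seed=0),
        )
        assert result.null_histogram == {0: 50}
        assert result.p_value == 1.0

    def test_observed_count_statistic(self):
        from helpers import make_record

        records = (
            [make_record("A1", "missense", gene_id="gX", position=i * 10)
             for i in range(3)]
            + [make_record("B1", "nonsense", gene_id="gX", position=500)]
            + [make_record("A2", "missense", gene_id="gY", position=600)]
            + [make_record("A3", "frameshift", gene_id="gZ", position=700)]
            + [make_record("A4", "frameshift", gene_id="gZ", position=800)]
        )
        assert observed_parallel_gene_count(records, snv_only=True) == 1
        assert observed_parallel_gene_count(records, snv_only=False) == 2
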