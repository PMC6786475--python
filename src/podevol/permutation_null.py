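"""Context-matched permutation nulls for effect-class counts and parallelism.

Observed SNVs are re-thrown onto the genome: each mutation lands uniformly
at random on a position whose forward-strand trinucleotide equals the
mutation's own context, keeping its substituted base.  Re-annotating each
replicate yields null distributions for the number of nonsense and missense
changes, and — pooling two founder lineages — for the number of genes hit by
at least two protein-altering single-nucleotide changes.  Empirical p is the
right tail: the fraction of replicates at or above the observed value.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .effect_annotation import (
    CODE_MISSENSE,
    CODE_NONSENSE,
    EffectLookup,
    _BASE_INDEX,
)
from .genome_model import FixationRecord, Genome

BLOCK_SIZE = 500  # replicates per seed block; results are thread-count invariant


@dataclass(frozen=True)
class ObservedSnv:
    """A mutation to re-throw: its 3-mer context (or None) and its alt base."""

    context: Optional[str]
    alt: str

    @classmethod
    def from_record(cls, record: FixationRecord) -> "ObservedSnv":
        if not record.variant.is_snv:
            raise ValueError("observed set must contain SNVs only")
        return cls(record.trinucleotide_context, record.variant.alt)


@dataclass(frozen=True)
class PermutationConfig:
    n_reps: int = 10_000
    seed: int = 0
    context_matched: bool = True
    collapse_strand: bool = False
    add_one: bool = False  # Davison-Hinkley (r+1)/(n+1) estimator
    threads: int = 1

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class PermutationResult:
    statistic: str
    observed: int
    null_histogram: Counter = field(default_factory=Counter)
    n_reps: int = 0
    add_one: bool = False

    @property
    def p_value(self) -> float:
        tail = sum(n for value, n in self.null_histogram.items()
                   if value >= self.observed)
        if self.add_one:
            return (tail + 1) / (self.n_reps + 1)
        return tail / self.n_reps

    def null_values(self) -> np.ndarray:
        return np.array(sorted(self.null_histogram.elements()))


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp3(kmer: str) -> str:
    return kmer.translate(_RC)[::-1]


def collapse_context(kmer: str) -> str:
    """Pyrimidine-centred representative of a 3-mer and its reverse complement."""
    return kmer if kmer[1] in "CT" else _revcomp3(kmer)


class ContextIndex:
    """Eligible genomic positions grouped by forward-strand trinucleotide.

    Positions are in the concatenated coordinate space of
    :class:`~podevol.effect_annotation.EffectLookup`.  Contig edges and
    N-containing windows are excluded; mutations with undefined context are
    drawn from the pooled uniform set of all eligible positions.
    """

    def __init__(self, genome: Genome, collapse_strand: bool = False):
        self.collapse_strand = collapse_strand
        positions: dict[str, list[np.ndarray]] = {}
        all_eligible: list[np.ndarray] = []
        offset = 0
        for cid, seq in genome.contigs.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            code = np.full(arr.shape, -1, dtype=np.int8)
            for base, idx in _BASE_INDEX.items():
                code[arr == ord(base)] = idx
            if len(arr) >= 3:
                tri = (16 * code[:-2] + 4 * code[1:-1] + code[2:])
                valid = (code[:-2] >= 0) & (code[1:-1] >= 0) & (code[2:] >= 0)
                pos = np.nonzero(valid)[0] + 1  # centre positions
                kcodes = tri[pos - 1]
                for k in np.unique(kcodes):
                    kmer = self._decode(int(k))
                    key = collapse_context(kmer) if collapse_strand else kmer
                    positions.setdefault(key, []).append(
                        pos[kcodes == k] + offset
                    )
                all_eligible.append(pos + offset)
            offset += len(seq)
        self.positions: dict[str, np.ndarray] = {
            k: np.sort(np.concatenate(v)) for k, v in positions.items()
        }
        self.all_eligible: np.ndarray = (
            np.sort(np.concatenate(all_eligible)) if all_eligible
            else np.empty(0, dtype=np.int64)
        )

    @staticmethod
    def _decode(code: int) -> str:
        b = "ACGT"
        return b[code // 16] + b[(code // 4) % 4] + b[code % 4]

    def eligible(self, context: Optional[str]) -> np.ndarray:
        """Positions matching a context; the uniform pool when undefined/absent."""
        if context is None:
            return self.all_eligible
        key = collapse_context(context) if self.collapse_strand else context
        return self.positions.get(key, self.all_eligible)

    def n_eligible(self) -> int:
        return int(self.all_eligible.size)


def build_context_index(genome: Genome, collapse_strand: bool = False) -> ContextIndex:
    return ContextIndex(genome, collapse_strand=collapse_strand)


def permute_once(
    observed: Sequence[ObservedSnv],
    index: ContextIndex,
    rng: np.random.Generator,
    context_matched: bool = True,
) -> np.ndarray:
    """Place each observed SNV on one random context-matching position.

    Returns the global positions, aligned with ``observed``.  Placement is
    with replacement across mutations (collisions allowed).
    """
    out = np.empty(len(observed), dtype=np.int64)
    for j, snv in enumerate(observed):
        pool = index.eligible(snv.context if context_matched else None)
        out[j] = pool[rng.integers(pool.size)]
    return out


def _placement_matrix(
    observed: Sequence[ObservedSnv],
    index: ContextIndex,
    n_reps: int,
    seed_seq: np.random.SeedSequence,
    context_matched: bool,
) -> np.ndarray:
    """(n_reps, n_mut) placements, drawn block-by-block with derived seeds."""
    out = np.empty((n_reps, len(observed)), dtype=np.int64)
    n_blocks = (n_reps + BLOCK_SIZE - 1) // BLOCK_SIZE
    children = seed_seq.spawn(n_blocks)
    for b in range(n_blocks):
        rng = np.random.default_rng(children[b])
        lo, hi = b * BLOCK_SIZE, min((b + 1) * BLOCK_SIZE, n_reps)
        for j, snv in enumerate(observed):
            pool = index.eligible(snv.context if context_matched else None)
            out[lo:hi, j] = pool[rng.integers(pool.size, size=hi - lo)]
    return out


def null_effect_counts(
    genome: Genome,
    lookup: EffectLookup,
    index: ContextIndex,
    observed_snvs: Sequence[ObservedSnv],
    observed_counts: dict[str, int],
    config: Optional[PermutationConfig] = None,
) -> dict[str, PermutationResult]:
    """Null distributions for the numbers of nonsense and missense SNVs.

    ``observed_counts`` holds the actually observed statistic values, e.g.
    {"nonsense": 8, "missense": 31}.
    """
    config = config or PermutationConfig()
    placements = _placement_matrix(
        observed_snvs, index, config.n_reps,
        np.random.SeedSequence(config.seed), config.context_matched,
    )
    alt_idx = np.array([_BASE_INDEX[s.alt] for s in observed_snvs])
    codes = lookup.effect[placements, alt_idx[None, :]]
    results = {}
    for name, code in (("nonsense", CODE_NONSENSE), ("missense", CODE_MISSENSE)):
        per_rep = (codes == code).sum(axis=1)
        results[name] = PermutationResult(
            statistic=f"{name}_count",
            observed=observed_counts[name],
            null_histogram=Counter(per_rep.tolist()),
            n_reps=config.n_reps,
            add_one=config.add_one,
        )
    return results


def null_parallel_genes(
    lookups: Sequence[EffectLookup],
    indexes: Sequence[ContextIndex],
    observed_sets: Sequence[Sequence[ObservedSnv]],
    observed_statistic: int,
    config: Optional[PermutationConfig] = None,
    min_hits: int = 2,
) -> PermutationResult:
    """Null for the number of genes with >= ``min_hits`` protein-altering SNVs.

    Each lineage's observed SNV set is thrown onto its own founder genome;
    protein-altering hits (missense + nonsense) are pooled by gene id across
    lineages before counting, so parallelism across lineages is captured
    through the shared gene namespace.
    """
    config = config or PermutationConfig()
    root = np.random.SeedSequence(config.seed)
    lineage_seeds = root.spawn(len(observed_sets))
    placements, alt_indices = [], []
    for lookup, index, observed, sseq in zip(
        lookups, indexes, observed_sets, lineage_seeds
    ):
        placements.append(_placement_matrix(
            observed, index, config.n_reps, sseq, config.context_matched,
        ))
        alt_indices.append(np.array([_BASE_INDEX[s.alt] for s in observed], dtype=np.int64))

    # map each lineage's local gene indices into one shared namespace
    name_to_shared: dict[str, int] = {}
    shared_maps = []
    for lookup in lookups:
        m = np.empty(len(lookup.gene_ids) + 1, dtype=np.int64)
        m[-1] = -1
        for i, gid in enumerate(lookup.gene_ids):
            m[i] = name_to_shared.setdefault(gid, len(name_to_shared))
        shared_maps.append(m)

    counts = np.zeros(config.n_reps, dtype=np.int64)
    per_lineage = []
    for lookup, placed, alt_idx, smap in zip(
        lookups, placements, alt_indices, shared_maps
    ):
        codes = lookup.effect[placed, alt_idx[None, :]]
        genes = smap[lookup.gene_index[placed, alt_idx[None, :]]]
        altering = (codes == CODE_MISSENSE) | (codes == CODE_NONSENSE)
        per_lineage.append((genes, altering))
    for r in range(config.n_reps):
        hit_genes = np.concatenate([
            genes[r][altering[r]] for genes, altering in per_lineage
        ])
        if hit_genes.size:
            _, per_gene = np.unique(hit_genes, return_counts=True)
            counts[r] = int((per_gene >= min_hits).sum())
    return PermutationResult(
        statistic=f"genes_with_ge{min_hits}_protein_altering_snvs",
        observed=observed_statistic,
        null_histogram=Counter(counts.tolist()),
        n_reps=config.n_reps,
        add_one=config.add_one,
    )


def observed_parallel_gene_count(
    records: Sequence[FixationRecord], min_hits: int = 2, snv_only: bool = True
) -> int:
    """Number of genes carrying >= ``min_hits`` protein-altering fixations.

    With ``snv_only`` (the permutation-comparable statistic) only missense
    and nonsense single-nucleotide changes count; otherwise frameshifts and
    in-frame indels count too (the tabulated parallel-protein summary).
    """
    hits = Counter()
    for rec in records:
        altering = rec.is_protein_altering_snv if snv_only else rec.is_protein_altering
        if altering and rec.gene_id is not None:
            hits[rec.gene_id] += 1
    return sum(1 for n in hits.values() if n >= min_hits)
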