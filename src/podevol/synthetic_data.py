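"""Synthetic serial-passage evolution experiments with a ground-truth ledger.

The generator emulates the study design being analyzed: eight clonal
populations founded from two lineages (five from A, three from B), sampled
at four passage timepoints, each accumulating fixations as a Poisson process
over passages.  It emits every input the pipeline consumes — founder genome
(FASTA), gene models (GFF3), low-complexity mask (BED), per-sample variant
tables (TSV/VCF), a validation matrix and pairwise ortholog alignments —
plus an :class:`ExperimentTruth` ledger naming every planted fixation and
every planted filter-triggering artifact, so downstream stages can be tested
for exact recovery.

Scale: the founder genome defaults to 3 Mb with ~330 genes (~10% coding).
Mutation counts stay at the real experiment's scale, which keeps the rate of
chance parallel hits per permutation replicate (proportional to
n_mutations x gene_length / genome_length) in the same regime as the full
35 Mb genome.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .effect_annotation import classify_indel, classify_snv
from .conservation_stats import OrthologPair, write_ortholog_pairs_tsv
from .genome_model import (
    GeneModel,
    Genome,
    MaskInterval,
    STOP_CODONS,
    VariantCall,
    evaluate_completeness,
    normalize_variant,
    revcomp,
    write_gene_models,
    write_genome,
    write_mask,
    write_variants_tsv,
    write_vcf,
)
from .variant_filtering import FounderEvidence

AMINO_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
)
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


class ConfigError(ValueError):
    """Raised when an experiment configuration is internally infeasible."""


@dataclass(frozen=True)
class ParallelTarget:
    """A gene planted to fix protein-altering mutations in many populations."""

    gene_rank: int                 # index into the generated gene list
    effect: str                    # missense | nonsense | frameshift
    populations: tuple[str, ...]   # which populations receive a hit

    def __post_init__(self) -> None:
        if self.effect not in ("missense", "nonsense", "frameshift"):
            raise ConfigError(f"unsupported parallel effect {self.effect!r}")


_A_POPS = ("A1", "A2", "A3", "A4", "A5")
_B_POPS = ("B1", "B2", "B3")

#: default parallel-target layout mirroring the six repeatedly hit proteins
#: of the study (one gene frameshifted in six populations, one missense gene
#: hit in seven, plus smaller two- and three-population targets)
DEFAULT_PARALLEL_TARGETS = (
    ParallelTarget(0, "frameshift", _A_POPS + ("B1",)),
    ParallelTarget(1, "missense", _A_POPS + ("B1", "B2")),
    ParallelTarget(2, "nonsense", ("A1", "A2", "B3")),
    ParallelTarget(3, "nonsense", ("A3", "B2")),
    ParallelTarget(4, "missense", ("A4", "B1")),
    ParallelTarget(5, "missense", ("A1", "A5", "B3")),
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one synthetic experiment.

    Defaults reproduce the analyzed experiment: 5 + 3 populations from two
    founder lineages, sequencing at passages 75/130/200/268, a fixation
    rate giving ~148 fixations overall (including the planted parallel
    hits), ~85% of fixations being SNVs and a 2:1 transition:transversion
    ratio.
    """

    seed: int = 0
    # genome
    n_contigs: int = 2
    contig_length: int = 1_500_000
    gene_density: float = 0.10          # target coding fraction of the genome
    mean_cds_length: int = 900          # nt, forced to a multiple of 3
    intron_probability: float = 0.30
    intron_length: int = 60
    incomplete_gene_fraction: float = 0.02
    n_masks_per_contig: int = 8
    mask_length: int = 120
    # experiment layout
    populations: tuple[str, ...] = _A_POPS + _B_POPS
    timepoints: tuple[int, ...] = (75, 130, 200, 268)
    # fixation process
    per_passage_fixation_rate: float = (148 - 23) / (8 * 268)  # background only
    snv_fraction: float = 125 / 148
    protein_altering_snv_fraction: float = 63 / 125
    synonymous_snv_fraction: float = 13 / 125
    indel_coding_fraction: float = 13 / 23
    transition_transversion_ratio: float = 2.0
    parallel_targets: tuple[ParallelTarget, ...] = DEFAULT_PARALLEL_TARGETS
    # sequencing evidence
    mean_depth: int = 40
    min_fixed_frequency: float = 0.95
    # planted artifacts (counts per experiment)
    n_low_coverage_artifacts: int = 8
    n_founder_supported_artifacts: int = 26
    n_multipopulation_artifacts: int = 2
    n_adjacent_pair_artifacts: int = 2
    n_masked_indel_artifacts: int = 4
    # validation behaviour
    n_unverifiable: int = 0
    n_time_unknown: int = 0
    # ortholog generation
    reliable_ortholog_fraction: float = 4713 / 10230
    conserved_site_fraction: float = 0.62

    def __post_init__(self) -> None:
        for name in ("gene_density", "snv_fraction",
                     "protein_altering_snv_fraction", "indel_coding_fraction",
                     "intron_probability", "incomplete_gene_fraction",
                     "reliable_ortholog_fraction", "conserved_site_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ConfigError("timepoints must be strictly increasing")
        if self.per_passage_fixation_rate < 0:
            raise ConfigError("negative fixation rate")


@dataclass(frozen=True)
class PlantedFixation:
    population: str
    contig: str
    position: int
    ref: str
    alt: str
    appearance_passage: int
    first_timepoint: int
    intended_effect: str
    gene_id: Optional[str]
    validation: str = "verified"      # verified | unverifiable | time_unknown

    def key(self) -> tuple:
        return (self.population, self.contig, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class PlantedArtifact:
    population: str
    contig: str
    position: int
    ref: str
    alt: str
    removing_filter: str

    def key(self) -> tuple:
        return (self.population, self.contig, self.position, self.ref, self.alt)


@dataclass
class ExperimentTruth:
    fixations: list[PlantedFixation] = field(default_factory=list)
    artifacts: list[PlantedArtifact] = field(default_factory=list)

    def fixation_keys(self) -> set[tuple]:
        return {f.key() for f in self.fixations}

    def recoverable_keys(self) -> set[tuple]:
        """Keys of planted fixations a validated pipeline should report."""
        return {f.key() for f in self.fixations if f.validation != "unverifiable"}


@dataclass
class SyntheticExperiment:
    """Everything one pipeline run consumes, plus the truth ledger."""

    genome: Genome
    gene_models: list[GeneModel]
    masks: list[MaskInterval]
    calls: list[VariantCall]
    founder: FounderEvidence
    validation: dict[tuple, dict[int, Optional[bool]]]
    truth: ExperimentTruth
    ortholog_pairs: list[OrthologPair]
    config: ExperimentConfig

    @property
    def sample_map(self) -> dict[str, tuple[str, int]]:
        return {
            f"{pop}_p{tp}": (pop, tp)
            for pop in self.config.populations
            for tp in self.config.timepoints
        }

    def ngs_presence(self) -> dict[tuple, dict[int, bool]]:
        present: dict[tuple, dict[int, bool]] = {}
        for c in self.calls:
            key = (c.population_id, c.contig, c.position, c.ref, c.alt)
            present.setdefault(
                key, {tp: False for tp in self.config.timepoints}
            )[c.timepoint] = True
        return present


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def generate_genome_and_annotation(
    config: ExperimentConfig,
) -> tuple[Genome, list[GeneModel], list[MaskInterval]]:
    """Generate a founder genome with complete genes and intergenic masks.

    Genes are written into the random background sequence codon-by-codon
    (ATG start, non-stop body, stop end), so they are complete by
    construction; a configurable fraction gets its start codon destroyed to
    produce incomplete genes.  Masked intervals are carved from intergenic
    gaps away from contig edges.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    mean_cds = max(150, config.mean_cds_length // 3 * 3)
    total_len = config.n_contigs * config.contig_length
    n_genes = int(round(config.gene_density * total_len / mean_cds))

    contigs: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    masks: list[MaskInterval] = []
    bases = np.frombuffer(b"ACGT", dtype="S1")
    gene_counter = 0
    genes_per_contig = _split_evenly(n_genes, config.n_contigs)
    mean_footprint = mean_cds + config.intron_probability * config.intron_length
    for ci in range(config.n_contigs):
        cid = f"contig_{ci + 1}"
        seq = rng.choice(bases, size=config.contig_length)
        gaps: list[tuple[int, int]] = []
        cursor = 150
        placed = 0
        target = genes_per_contig[ci]
        while placed < target:
            # budget the remaining intergenic space over the genes still due,
            # so the target count is met even on small contigs
            remaining_genes = target - placed
            space_left = config.contig_length - 150 - cursor
            gap_budget = space_left - remaining_genes * mean_footprint
            gap_mean = gap_budget / remaining_genes
            if gap_mean < 30:
                raise ConfigError(
                    f"gene_density {config.gene_density} infeasible: "
                    f"no room for gene {placed + 1}/{target} on {cid}"
                )
            gap = int(rng.uniform(0.6 * gap_mean, 1.4 * gap_mean))
            max_footprint = mean_cds * 3 // 2 + config.intron_length + 30
            gap = max(30, min(gap, int(space_left - max_footprint)))
            gene_start = cursor + gap
            cds_len = int(rng.integers(mean_cds // 2, mean_cds * 3 // 2)) // 3 * 3
            cds_len = max(150, cds_len)
            has_intron = rng.random() < config.intron_probability
            span = cds_len + (config.intron_length if has_intron else 0)
            while gene_start + span + 150 > config.contig_length and cds_len > 150:
                cds_len -= 30
                span = cds_len + (config.intron_length if has_intron else 0)
            if gene_start + span + 150 > config.contig_length:
                raise ConfigError(
                    f"gene_density {config.gene_density} infeasible: "
                    f"gene {placed + 1}/{target} does not fit on {cid}"
                )
            gaps.append((cursor, gene_start))
            gene_counter += 1
            gid = f"g{gene_counter:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            incomplete = rng.random() < config.incomplete_gene_fraction
            coding = _random_cds(cds_len, rng, broken_start=incomplete)
            if has_intron:
                cut = int(rng.integers(1, cds_len // 3)) * 3
                seg_a = (gene_start, gene_start + cut)
                seg_b = (
                    gene_start + cut + config.intron_length,
                    gene_start + span,
                )
                segs_genomic = [seg_a, seg_b]
            else:
                segs_genomic = [(gene_start, gene_start + span)]
            _write_coding(seq, segs_genomic, coding, strand)
            segs = segs_genomic if strand == "+" else segs_genomic[::-1]
            genes.append(GeneModel(gid, cid, strand, tuple(segs),
                                   complete=not incomplete))
            cursor = gene_start + span
            placed += 1
        gaps.append((cursor, config.contig_length - 150))
        # carve masks from the widest intergenic gaps
        wide = [g for g in gaps if g[1] - g[0] >= config.mask_length + 60]
        rng.shuffle(wide)
        for g in wide[: config.n_masks_per_contig]:
            mid = (g[0] + g[1]) // 2
            masks.append(MaskInterval(
                cid, mid - config.mask_length // 2,
                mid - config.mask_length // 2 + config.mask_length,
            ))
        contigs[cid] = seq

    genome = Genome({
        cid: arr.tobytes().decode() for cid, arr in contigs.items()
    })
    for g in genes:
        assert evaluate_completeness(g, genome) == g.complete, g.gene_id
    return genome, genes, sorted(masks)


def _split_evenly(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _random_cds(length: int, rng: np.random.Generator,
                broken_start: bool = False) -> str:
    n_body = length // 3 - 2
    body = "".join(
        AMINO_CODONS[i] for i in rng.integers(len(AMINO_CODONS), size=n_body)
    )
    stop = sorted(STOP_CODONS)[int(rng.integers(3))]
    start = "ATG" if not broken_start else "CTG"
    return start + body + stop


def _write_coding(seq: np.ndarray, segs_genomic: Sequence[tuple[int, int]],
                  coding: str, strand: str) -> None:
    written = coding if strand == "+" else revcomp(coding)
    off = 0
    for s, e in segs_genomic:
        chunk = written[off : off + (e - s)]
        seq[s:e] = np.frombuffer(chunk.encode(), dtype="S1")
        off += e - s


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

class _Placer:
    """Rejection-samples mutation sites subject to the artifact-free rules."""

    def __init__(self, genome: Genome, genes: list[GeneModel],
                 masks: list[MaskInterval], config: ExperimentConfig,
                 rng: np.random.Generator):
        self.genome = genome
        self.genes = genes
        self.complete_genes = [g for g in genes if g.complete]
        self.masks = masks
        self.config = config
        self.rng = rng
        self.contig_ids = list(genome.contigs)
        self.lengths = genome.lengths()
        # sites already used, per population (adjacency + duplicates guard)
        self.used: dict[str, set[tuple[str, int]]] = {}
        # true indels must clear the mask flank (10 bp) with one spare base
        self.expanded_masks = [
            (m.contig, m.start - 11, m.end + 11) for m in masks
        ]

    def _site_free(self, population: str, contig: str, position: int,
                   min_dist: int = 2) -> bool:
        used = self.used.setdefault(population, set())
        return not any(
            (contig, position + d) in used
            for d in range(-min_dist, min_dist + 1)
        )

    def _claim(self, population: str, contig: str, position: int) -> None:
        self.used.setdefault(population, set()).add((contig, position))

    def _in_masked(self, contig: str, position: int) -> bool:
        return any(
            c == contig and s <= position < e for c, s, e in self.expanded_masks
        )

    def random_snv(self, population: str,
                   target: Optional[str] = None) -> VariantCall | None:
        """One SNV; ``target`` 'protein_altering' forces missense/nonsense,
        'synonymous' a silent coding change, None places uniformly."""
        wanted = {
            "protein_altering": ("missense", "nonsense"),
            "synonymous": ("synonymous",),
            None: None,
        }[target]
        for _ in range(500):
            if wanted is not None:
                gene = self.complete_genes[
                    int(self.rng.integers(len(self.complete_genes)))
                ]
                seg_lens = [e - s for s, e in gene.cds_segments]
                seg = int(self.rng.choice(
                    len(seg_lens), p=np.array(seg_lens) / sum(seg_lens)
                ))
                s, e = gene.cds_segments[seg]
                pos = int(self.rng.integers(s, e))
                contig = gene.contig
            else:
                contig = self.contig_ids[int(self.rng.integers(len(self.contig_ids)))]
                pos = int(self.rng.integers(1, self.lengths[contig] - 1))
            ref = self.genome[contig][pos]
            alt = self._draw_alt(ref)
            if not self._site_free(population, contig, pos):
                continue
            call = _call_stub(contig, pos, ref, alt)
            cls = classify_snv(call, self.genes, self.genome)
            if wanted is not None and cls.effect not in wanted:
                continue
            self._claim(population, contig, pos)
            return call
        return None

    def targeted_snv(self, population: str, gene: GeneModel,
                     effect: str) -> VariantCall:
        for _ in range(2000):
            seg_lens = [e - s for s, e in gene.cds_segments]
            seg = int(self.rng.choice(
                len(seg_lens), p=np.array(seg_lens) / sum(seg_lens)
            ))
            s, e = gene.cds_segments[seg]
            pos = int(self.rng.integers(s, e))
            ref = self.genome[gene.contig][pos]
            alt = self._draw_alt(ref)
            if not self._site_free(population, gene.contig, pos):
                continue
            call = _call_stub(gene.contig, pos, ref, alt)
            if classify_snv(call, self.genes, self.genome).effect != effect:
                continue
            self._claim(population, gene.contig, pos)
            return call
        raise ConfigError(
            f"could not plant a {effect} SNV in {gene.gene_id}"
        )

    def random_indel(self, population: str, coding: bool,
                     gene: Optional[GeneModel] = None,
                     frameshift: bool = True) -> VariantCall:
        for _ in range(2000):
            if coding:
                g = gene or self.complete_genes[
                    int(self.rng.integers(len(self.complete_genes)))
                ]
                s, e = max(g.cds_segments, key=lambda se: se[1] - se[0])
                pos = int(self.rng.integers(s + 1, e - 4))
                contig = g.contig
            else:
                contig = self.contig_ids[int(self.rng.integers(len(self.contig_ids)))]
                pos = int(self.rng.integers(20, self.lengths[contig] - 20))
            length = (int(self.rng.choice([1, 2, 4])) if frameshift else 3)
            seq = self.genome[contig]
            if self.rng.random() < 0.5:
                ref, alt = seq[pos : pos + length], ""
            else:
                ins = "".join(
                    "ACGT"[i] for i in self.rng.integers(4, size=length)
                )
                ref, alt = "", ins
            npos, nref, nalt = normalize_variant(pos, ref, alt, seq)
            if self._in_masked(contig, npos):
                continue
            if not self._site_free(population, contig, npos):
                continue
            call = _call_stub(contig, npos, nref, nalt)
            cls = classify_indel(call, self.genes)
            if coding and cls.effect not in ("frameshift", "inframe_indel"):
                continue
            if coding and gene is not None and cls.gene_id != gene.gene_id:
                continue
            self._claim(population, contig, npos)
            return call
        raise ConfigError("could not place an indel under the constraints")

    def _draw_alt(self, ref: str) -> str:
        r = self.config.transition_transversion_ratio
        if self.rng.random() < r / (r + 1.0):
            return _TS_PARTNER[ref]
        tv = [b for b in "ACGT" if b != ref and b != _TS_PARTNER[ref]]
        return tv[int(self.rng.integers(2))]


def _call_stub(contig: str, pos: int, ref: str, alt: str) -> VariantCall:
    return VariantCall(contig, pos, ref, alt, "stub", 40, 40, 1.0)


def simulate_experiment(
    genome: Genome,
    gene_models: list[GeneModel],
    masks: list[MaskInterval],
    config: ExperimentConfig,
) -> SyntheticExperiment:
    """Simulate fixations, artifacts and evidence for one experiment.

    Fixations arise per population as a Poisson process over passages and
    persist at every later timepoint (presence is monotone by construction).
    Fixed variants carry deep coverage and near-1 frequency; each planted
    artifact class carries exactly the evidence pattern that its designated
    exclusion rule keys on.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    placer = _Placer(genome, gene_models, masks, config, rng)
    founder = FounderEvidence(default_coverage=config.mean_depth)
    truth = ExperimentTruth()
    total_passages = max(config.timepoints) if config.timepoints else 0

    planted: list[tuple[PlantedFixation, VariantCall]] = []

    # --- background fixations -------------------------------------------
    for pop in config.populations:
        n_fix = int(rng.poisson(config.per_passage_fixation_rate * total_passages))
        for _ in range(n_fix):
            passage = int(rng.integers(1, total_passages + 1))
            if rng.random() < config.snv_fraction:
                u = rng.random()
                if u < config.protein_altering_snv_fraction:
                    target = "protein_altering"
                elif u < (config.protein_altering_snv_fraction
                          + config.synonymous_snv_fraction):
                    target = "synonymous"
                else:
                    target = None
                call = placer.random_snv(pop, target=target)
                if call is None:
                    continue
            else:
                coding = rng.random() < config.indel_coding_fraction
                frameshift = rng.random() < 0.8
                call = placer.random_indel(pop, coding, frameshift=frameshift)
            planted.append(_record_fixation(
                call, pop, passage, config, genome, gene_models
            ))

    # --- parallel targets ------------------------------------------------
    complete = [g for g in gene_models if g.complete]
    for target in config.parallel_targets:
        if target.gene_rank >= len(complete):
            raise ConfigError(
                f"parallel target rank {target.gene_rank} out of range"
            )
        gene = complete[target.gene_rank]
        for pop in target.populations:
            if pop not in config.populations:
                raise ConfigError(f"unknown population {pop!r} in parallel target")
            passage = int(rng.integers(1, total_passages + 1))
            if target.effect == "frameshift":
                call = placer.random_indel(pop, coding=True, gene=gene,
                                           frameshift=True)
            else:
                call = placer.targeted_snv(pop, gene, target.effect)
            planted.append(_record_fixation(
                call, pop, passage, config, genome, gene_models
            ))

    # --- validation categories ------------------------------------------
    rng.shuffle(planted)
    n_unv = min(config.n_unverifiable, len(planted))
    n_tu = min(config.n_time_unknown, max(0, len(planted) - n_unv))
    relabelled = []
    for i, (fx, call) in enumerate(planted):
        if i < n_unv:
            fx = dataclasses.replace(fx, validation="unverifiable")
        elif i < n_unv + n_tu:
            fx = dataclasses.replace(
                fx, validation="time_unknown",
                first_timepoint=max(config.timepoints),
            )
        relabelled.append((fx, call))
    planted = sorted(
        relabelled, key=lambda t: (t[0].population, t[0].contig, t[0].position)
    )
    truth.fixations = [fx for fx, _ in planted]

    # --- evidence for true fixations -------------------------------------
    calls: list[VariantCall] = []
    validation: dict[tuple, dict[int, Optional[bool]]] = {}
    for fx, proto in planted:
        present_tps = [tp for tp in config.timepoints if tp >= fx.first_timepoint]
        for tp in present_tps:
            calls.append(_with_evidence(proto, fx.population, tp, config, rng))
        if fx.validation == "verified":
            validation[fx.key()] = {
                tp: tp in present_tps for tp in config.timepoints
            }
        elif fx.validation == "unverifiable":
            validation[fx.key()] = {tp: None for tp in config.timepoints}
        else:  # time_unknown: assay failed before the final timepoint
            validation[fx.key()] = {
                tp: (True if tp == max(config.timepoints) else None)
                for tp in config.timepoints
            }

    # --- artifacts --------------------------------------------------------
    final_tp = max(config.timepoints)
    art_calls, artifacts = _plant_artifacts(placer, founder, config, rng, final_tp)
    calls.extend(art_calls)
    truth.artifacts = artifacts

    pairs = _generate_ortholog_pairs(genome, gene_models, config, rng)

    return SyntheticExperiment(
        genome=genome, gene_models=gene_models, masks=masks,
        calls=calls, founder=founder, validation=validation,
        truth=truth, ortholog_pairs=pairs, config=config,
    )


def _record_fixation(
    call: VariantCall, pop: str, passage: int, config: ExperimentConfig,
    genome: Genome, gene_models: list[GeneModel],
) -> tuple[PlantedFixation, VariantCall]:
    later = [tp for tp in config.timepoints if tp >= passage]
    first_tp = later[0] if later else max(config.timepoints)
    if call.is_snv:
        cls = classify_snv(call, gene_models, genome)
        effect, gene_id = cls.effect, cls.gene_id
    else:
        cls = classify_indel(call, gene_models)
        effect, gene_id = cls.effect, cls.gene_id
    fx = PlantedFixation(
        population=pop, contig=call.contig, position=call.position,
        ref=call.ref, alt=call.alt, appearance_passage=passage,
        first_timepoint=first_tp, intended_effect=effect, gene_id=gene_id,
    )
    return fx, call


def _with_evidence(
    proto: VariantCall, pop: str, tp: int, config: ExperimentConfig,
    rng: np.random.Generator,
) -> VariantCall:
    coverage = max(
        config.mean_depth // 2,
        int(rng.normal(config.mean_depth, config.mean_depth / 5)),
    )
    freq = float(rng.uniform(config.min_fixed_frequency, 1.0))
    alt_reads = min(coverage, int(round(freq * coverage)))
    return VariantCall(
        proto.contig, proto.position, proto.ref, proto.alt,
        sample_id=f"{pop}_p{tp}", coverage=coverage, alt_reads=alt_reads,
        frequency=alt_reads / coverage, population_id=pop, timepoint=tp,
    )


def _plant_artifacts(
    placer: _Placer, founder: FounderEvidence, config: ExperimentConfig,
    rng: np.random.Generator, final_tp: int,
) -> tuple[list[VariantCall], list[PlantedArtifact]]:
    calls: list[VariantCall] = []
    artifacts: list[PlantedArtifact] = []
    pops = list(config.populations)

    def good_evidence(proto: VariantCall, pop: str) -> VariantCall:
        return _with_evidence(proto, pop, final_tp, config, rng)

    # low-coverage calls: fail the quality rule
    for _ in range(config.n_low_coverage_artifacts):
        pop = pops[int(rng.integers(len(pops)))]
        proto = placer.random_snv(pop)
        if proto is None:
            continue
        cov = int(rng.integers(3, config.mean_depth // 4 if config.mean_depth >= 16 else 4))
        cov = min(cov, 9)
        calls.append(VariantCall(
            proto.contig, proto.position, proto.ref, proto.alt,
            sample_id=f"{pop}_p{final_tp}", coverage=cov, alt_reads=cov,
            frequency=1.0, population_id=pop, timepoint=final_tp,
        ))
        artifacts.append(PlantedArtifact(
            pop, proto.contig, proto.position, proto.ref, proto.alt, "quality"
        ))

    # founder-supported variants: ancestral alleles, removed by the founder rule
    for _ in range(config.n_founder_supported_artifacts):
        pop = pops[int(rng.integers(len(pops)))]
        proto = placer.random_snv(pop)
        if proto is None:
            continue
        founder.set(
            pop[0], proto.contig, proto.position, proto.alt,
            coverage=config.mean_depth, alt_reads=int(rng.integers(2, 6)),
        )
        calls.append(good_evidence(proto, pop))
        artifacts.append(PlantedArtifact(
            pop, proto.contig, proto.position, proto.ref, proto.alt, "founder"
        ))

    # shared variants at founder-uncovered sites: multi-population rule
    lineage_a_pops = [p for p in pops if p.startswith(pops[0][0])]
    for _ in range(config.n_multipopulation_artifacts):
        if len(lineage_a_pops) < 2:
            break
        p1, p2 = lineage_a_pops[:2]
        proto = placer.random_snv(p1)
        if proto is None:
            continue
        placer._claim(p2, proto.contig, proto.position)
        founder.set(p1[0], proto.contig, proto.position, proto.alt,
                    coverage=0, alt_reads=0)
        for pop in (p1, p2):
            calls.append(good_evidence(proto, pop))
            artifacts.append(PlantedArtifact(
                pop, proto.contig, proto.position, proto.ref, proto.alt,
                "multi_population",
            ))

    # adjacent dinucleotide pairs: both members removed by the adjacency rule
    for _ in range(config.n_adjacent_pair_artifacts):
        pop = pops[int(rng.integers(len(pops)))]
        proto = placer.random_snv(pop)
        if proto is None:
            continue
        seq = placer.genome[proto.contig]
        pos2 = proto.position + 1
        ref2 = seq[pos2]
        alt2 = placer._draw_alt(ref2)
        placer._claim(pop, proto.contig, pos2)
        second = VariantCall(proto.contig, pos2, ref2, alt2, "stub", 40, 40, 1.0)
        for p in (proto, second):
            calls.append(good_evidence(p, pop))
            artifacts.append(PlantedArtifact(
                pop, p.contig, p.position, p.ref, p.alt, "adjacency"
            ))

    # indels inside masked regions: mask-proximity rule
    mask_pool = placer.masks
    for i in range(config.n_masked_indel_artifacts):
        if not mask_pool:
            break
        pop = pops[int(rng.integers(len(pops)))]
        m = mask_pool[i % len(mask_pool)]
        pos = (m.start + m.end) // 2 + int(rng.integers(-10, 11))
        seq = placer.genome[m.contig]
        npos, nref, nalt = normalize_variant(pos, seq[pos], "", seq)
        # the rule removes indels inside mask +- 10 bp; re-check after
        # left-alignment so the planted call is guaranteed inside
        if not (m.start - 10 <= npos < m.end + 10):
            continue
        if not placer._site_free(pop, m.contig, npos):
            continue
        placer._claim(pop, m.contig, npos)
        proto = VariantCall(m.contig, npos, nref, nalt, "stub", 40, 40, 1.0)
        calls.append(good_evidence(proto, pop))
        artifacts.append(PlantedArtifact(
            pop, m.contig, npos, nref, nalt, "mask"
        ))

    return calls, artifacts


# ---------------------------------------------------------------------------
# Ortholog pair generation
# ---------------------------------------------------------------------------

def _generate_ortholog_pairs(
    genome: Genome, gene_models: list[GeneModel], config: ExperimentConfig,
    rng: np.random.Generator,
) -> list[OrthologPair]:
    """Pairwise alignments against a simulated outgroup proteome.

    A ``reliable_ortholog_fraction`` of complete proteins get a low-gap
    ortholog whose sites are conserved at ``conserved_site_fraction``; a
    small extra set gets a gap-heavy (unreliable) ortholog.  Real ortholog
    alignments differ in having indel blocks and rate heterogeneity along
    the sequence; neither matters to the column-wise statistics computed
    downstream.
    """
    from .genome_model import translate_cds

    aas = "ACDEFGHIKLMNPQRSTVWY"
    pairs: list[OrthologPair] = []
    for gene in gene_models:
        if not gene.complete:
            continue
        u = rng.random()
        protein = translate_cds(gene.spliced_cds(genome))[:-1]
        if u < config.reliable_ortholog_fraction:
            gap_target = 0.02
        elif u < config.reliable_ortholog_fraction + 0.08:
            gap_target = 0.35   # present but unreliable alignment
        else:
            continue
        focal, orth = [], []
        for res in protein:
            if rng.random() < gap_target:
                focal.append(res)
                orth.append("-")
                continue
            focal.append(res)
            if rng.random() < config.conserved_site_fraction:
                orth.append(res)
            else:
                choices = [a for a in aas if a != res]
                orth.append(choices[int(rng.integers(len(choices)))])
        pairs.append(OrthologPair(
            gene.gene_id, f"NC_{gene.gene_id}",
            "".join(focal), "".join(orth),
        ))
    return pairs


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_experiment(exp: SyntheticExperiment, outdir: str | Path,
                     vcf: bool = True) -> dict[str, Path]:
    """Write every pipeline input to ``outdir``; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "founder.fasta",
        "genes": outdir / "genes.gff3",
        "mask": outdir / "mask.bed",
        "variants": outdir / "variants.tsv",
        "validation": outdir / "validation.tsv",
        "truth": outdir / "truth.tsv",
        "orthologs": outdir / "orthologs.tsv",
        "founder_evidence": outdir / "founder_evidence.tsv",
    }
    write_genome(exp.genome, paths["genome"])
    write_gene_models(exp.gene_models, paths["genes"])
    write_mask(exp.masks, paths["mask"])
    write_variants_tsv(exp.calls, paths["variants"])
    if vcf:
        paths["vcf"] = outdir / "variants.vcf"
        write_vcf(exp.calls, exp.genome, paths["vcf"])
    with open(paths["validation"], "w") as fh:
        tps = exp.config.timepoints
        fh.write("population\tcontig\tposition\tref\talt\t"
                 + "\t".join(f"p{t}" for t in tps) + "\n")
        for key, row in sorted(exp.validation.items()):
            pop, contig, pos, ref, alt = key
            cells = ["NA" if row[t] is None else ("1" if row[t] else "0")
                     for t in tps]
            fh.write(f"{pop}\t{contig}\t{pos}\t{ref or '.'}\t{alt or '.'}\t"
                     + "\t".join(cells) + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("kind\tpopulation\tcontig\tposition\tref\talt\t"
                 "appearance_passage\tfirst_timepoint\teffect\tgene_id\t"
                 "validation\tremoving_filter\n")
        for f in exp.truth.fixations:
            fh.write(
                f"fixation\t{f.population}\t{f.contig}\t{f.position}\t"
                f"{f.ref or '.'}\t{f.alt or '.'}\t{f.appearance_passage}\t"
                f"{f.first_timepoint}\t{f.intended_effect}\t"
                f"{f.gene_id or '.'}\t{f.validation}\t.\n"
            )
        for a in exp.truth.artifacts:
            fh.write(
                f"artifact\t{a.population}\t{a.contig}\t{a.position}\t"
                f"{a.ref or '.'}\t{a.alt or '.'}\t.\t.\t.\t.\t.\t"
                f"{a.removing_filter}\n"
            )
    write_ortholog_pairs_tsv(exp.ortholog_pairs, paths["orthologs"])
    with open(paths["founder_evidence"], "w") as fh:
        fh.write("lineage\tcontig\tposition\talt\tcoverage\talt_reads\n")
        fh.write(f"#default_coverage={exp.founder.default_coverage}\n")
        for (lin, contig, pos, alt), (cov, ar) in sorted(exp.founder.items()):
            fh.write(f"{lin}\t{contig}\t{pos}\t{alt or '.'}\t{cov}\t{ar}\n")
    return paths


def generate_experiment(config: Optional[ExperimentConfig] = None
                        ) -> SyntheticExperiment:
    """Generate genome, annotation and simulated experiment in one call."""
    config = config or ExperimentConfig()
    genome, genes, masks = generate_genome_and_annotation(config)
    return simulate_experiment(genome, genes, masks, config)
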