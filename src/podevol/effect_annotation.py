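"""Variant effect classification against gene models.

Each variant gets exactly one effect class out of {missense, nonsense,
synonymous, intronic, intergenic, frameshift, inframe_indel,
incomplete_gene, unaligned}.  For SNVs inside the CDS of a complete gene the
affected codon is translated before and after the change (reverse
complementing for minus-strand genes).  Variants overlapping two genes are
classified against each and the most severe class is reported; the other
classifications are kept in the record's audit trail.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome_model import (
    CODON_TABLE,
    DataIntegrityError,
    FixationRecord,
    GeneModel,
    Genome,
    MaskInterval,
    VariantCall,
    revcomp,
    trinucleotide_context,
)

#: most-severe-first ranking used when a variant hits overlapping genes
SEVERITY_ORDER = (
    "nonsense", "frameshift", "missense", "inframe_indel", "synonymous",
    "incomplete_gene", "intronic",
)
_SEVERITY = {e: i for i, e in enumerate(SEVERITY_ORDER)}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def is_stop_codon(codon: str) -> bool:
    """True for the three standard stop codons TAA/TAG/TGA."""
    return CODON_TABLE.get(codon.upper()) == "*"


@dataclass(frozen=True)
class SnvClassification:
    effect: str
    gene_id: Optional[str]
    codon_index: Optional[int] = None
    residue_change: Optional[tuple[str, str]] = None


def _classify_snv_in_gene(
    gene: GeneModel, genome: Genome, position: int, alt: str
) -> SnvClassification:
    """Classify an SNV known to fall inside the genomic span of ``gene``."""
    off = gene.cds_offset(position)
    if off is None:
        return SnvClassification("intronic", gene.gene_id)
    if not gene.complete:
        return SnvClassification("incomplete_gene", gene.gene_id)
    cds = gene.spliced_cds(genome)
    alt_coding = alt if gene.strand == "+" else _COMP[alt]
    codon_i = off // 3
    within = off % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    new_codon = codon[:within] + alt_coding + codon[within + 1 :]
    aa_ref = CODON_TABLE[codon]
    aa_alt = CODON_TABLE[new_codon]
    if aa_alt == aa_ref:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    else:
        # includes stop-loss at the terminal codon: closest existing class
        effect = "missense"
    return SnvClassification(
        effect, gene.gene_id, codon_i, (aa_ref, aa_alt)
    )


def classify_snv(
    variant: VariantCall,
    gene_models: Sequence[GeneModel],
    genome: Genome,
    unaligned_regions: Sequence[MaskInterval] = (),
) -> SnvClassification:
    """Classify a single-nucleotide variant.

    ``unaligned_regions`` marks genome stretches without annotation liftover;
    variants inside them are tagged 'unaligned' rather than 'intergenic'.
    """
    if not variant.is_snv:
        raise ValueError("classify_snv requires an SNV")
    seq = genome[variant.contig]
    if seq[variant.position] != variant.ref:
        raise DataIntegrityError(
            f"{variant.contig}:{variant.position}: ref {variant.ref!r} does not "
            f"match genome base {seq[variant.position]!r}"
        )
    hits = [
        _classify_snv_in_gene(g, genome, variant.position, variant.alt)
        for g in gene_models
        if g.contig == variant.contig and g.contains(variant.position)
    ]
    if hits:
        hits.sort(key=lambda h: _SEVERITY[h.effect])
        return hits[0]
    if _in_regions(variant, unaligned_regions):
        return SnvClassification("unaligned", None)
    return SnvClassification("intergenic", None)


@dataclass(frozen=True)
class IndelClassification:
    effect: str
    gene_id: Optional[str]


def classify_indel(
    variant: VariantCall,
    gene_models: Sequence[GeneModel],
    unaligned_regions: Sequence[MaskInterval] = (),
) -> IndelClassification:
    """Classify an insertion or deletion by its leftmost affected base."""
    if variant.is_snv:
        raise ValueError("classify_indel requires an indel")
    hits = []
    for g in gene_models:
        if g.contig != variant.contig or not g.contains(variant.position):
            continue
        if not g.in_cds(variant.position):
            hits.append(IndelClassification("intronic", g.gene_id))
        elif not g.complete:
            hits.append(IndelClassification("incomplete_gene", g.gene_id))
        elif variant.indel_length % 3:
            hits.append(IndelClassification("frameshift", g.gene_id))
        else:
            hits.append(IndelClassification("inframe_indel", g.gene_id))
    if hits:
        hits.sort(key=lambda h: _SEVERITY[h.effect])
        return hits[0]
    if _in_regions(variant, unaligned_regions):
        return IndelClassification("unaligned", None)
    return IndelClassification("intergenic", None)


def _in_regions(variant: VariantCall, regions: Sequence[MaskInterval]) -> bool:
    return any(
        r.contig == variant.contig and r.start <= variant.position < r.end
        for r in regions
    )


def annotate_variant(
    variant: VariantCall,
    gene_models: Sequence[GeneModel],
    genome: Genome,
    unaligned_regions: Sequence[MaskInterval] = (),
) -> FixationRecord:
    """Produce a FixationRecord (effect, gene, residue change, context)."""
    if variant.is_snv:
        c = classify_snv(variant, gene_models, genome, unaligned_regions)
        context = trinucleotide_context(genome, variant.contig, variant.position)
        secondary = tuple(
            (h.gene_id or "", h.effect)
            for h in sorted(
                (
                    _classify_snv_in_gene(g, genome, variant.position, variant.alt)
                    for g in gene_models
                    if g.contig == variant.contig and g.contains(variant.position)
                ),
                key=lambda h: _SEVERITY[h.effect],
            )[1:]
        )
        return FixationRecord(
            variant=variant,
            population_id=variant.population_id or variant.sample_id,
            effect=c.effect,
            gene_id=c.gene_id,
            codon_index=c.codon_index,
            residue_change=c.residue_change,
            trinucleotide_context=context,
            first_seen_timepoint=variant.timepoint,
            secondary_effects=secondary,
        )
    c = classify_indel(variant, gene_models, unaligned_regions)
    return FixationRecord(
        variant=variant,
        population_id=variant.population_id or variant.sample_id,
        effect=c.effect,
        gene_id=c.gene_id,
        first_seen_timepoint=variant.timepoint,
    )


def annotate_variants(
    variants: Iterable[VariantCall],
    gene_models: Sequence[GeneModel],
    genome: Genome,
    unaligned_regions: Sequence[MaskInterval] = (),
) -> list[FixationRecord]:
    return [
        annotate_variant(v, gene_models, genome, unaligned_regions)
        for v in variants
    ]


# ---------------------------------------------------------------------------
# Vectorized effect lookup for permutation replicates
# ---------------------------------------------------------------------------

EFFECT_CODES = {
    "intergenic": 0, "intronic": 1, "synonymous": 2, "missense": 3,
    "nonsense": 4, "incomplete_gene": 5,
}
CODE_MISSENSE = EFFECT_CODES["missense"]
CODE_NONSENSE = EFFECT_CODES["nonsense"]
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"


class EffectLookup:
    """Precomputed (position, alt base) -> effect code / gene index tables.

    Built once per genome+annotation; lets a permutation replicate classify
    thousands of placed SNVs with two array lookups.  Contigs are
    concatenated into one coordinate space (see ``offsets``).  Where genes
    overlap, the most severe effect (and its gene) wins, matching
    :func:`classify_snv`.
    """

    def __init__(self, genome: Genome, gene_models: Sequence[GeneModel]):
        self.contig_ids = list(genome.contigs)
        self.offsets: dict[str, int] = {}
        off = 0
        for cid in self.contig_ids:
            self.offsets[cid] = off
            off += len(genome[cid])
        self.total_length = off
        self.gene_ids = [g.gene_id for g in gene_models]
        # effect code per (global position, alt base index); default intergenic
        self.effect = np.zeros((off, 4), dtype=np.int8)
        self.gene_index = np.full((off, 4), -1, dtype=np.int32)
        severity = np.array(
            [_SEVERITY.get(e, 99) for e in EFFECT_CODES], dtype=np.int8
        )
        code_of = EFFECT_CODES
        for gi, gene in enumerate(gene_models):
            base = self.offsets[gene.contig]
            seq = genome[gene.contig]
            span_s, span_e = gene.span
            cds = gene.spliced_cds(genome) if gene.complete else ""
            for pos in range(span_s, span_e):
                offcds = gene.cds_offset(pos)
                if offcds is None:
                    codes = [code_of["intronic"]] * 4
                elif not gene.complete:
                    codes = [code_of["incomplete_gene"]] * 4
                else:
                    ci, within = divmod(offcds, 3)
                    codon = cds[ci * 3 : ci * 3 + 3]
                    aa_ref = CODON_TABLE[codon]
                    codes = []
                    for b in BASES:
                        if b == seq[pos]:
                            codes.append(-1)  # not a substitution
                            continue
                        alt_c = b if gene.strand == "+" else _COMP[b]
                        new = codon[:within] + alt_c + codon[within + 1 :]
                        aa_alt = CODON_TABLE[new]
                        if aa_alt == aa_ref:
                            codes.append(code_of["synonymous"])
                        elif aa_alt == "*":
                            codes.append(code_of["nonsense"])
                        else:
                            codes.append(code_of["missense"])
                g = base + pos
                for bi, code in enumerate(codes):
                    if code < 0:
                        continue
                    old = self.effect[g, bi]
                    if old == 0 or severity[code] < severity[old]:
                        self.effect[g, bi] = code
                        self.gene_index[g, bi] = gi

    def global_position(self, contig: str, position: int) -> int:
        return self.offsets[contig] + position

    def effect_codes(self, positions: np.ndarray, alt_idx: np.ndarray) -> np.ndarray:
        return self.effect[positions, alt_idx]

    def gene_indices(self, positions: np.ndarray, alt_idx: np.ndarray) -> np.ndarray:
        return self.gene_index[positions, alt_idx]
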