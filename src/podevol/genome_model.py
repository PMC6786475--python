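"""Core domain types and I/O for the serial-passage evolution pipeline.

Internal coordinates are 0-based half-open on the forward strand everywhere.
GFF3 and VCF I/O convert from/to their native 1-based conventions at the
boundary; BED is consumed as-is (already 0-based half-open).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

#: forward translation table for the standard genetic code, stops mapped to '*'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: "*" for c in STOP_CODONS})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class DataIntegrityError(ValueError):
    """Raised when records contradict each other or the genome sequence."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str) -> str:
    """Translate a nucleotide string codon-by-codon; stops become '*'."""
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    return "".join(CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq), 3))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """A founder genome: mapping of contig id to an A/C/G/T/N string."""

    contigs: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise FormatError("genome has no contigs")
        for cid, seq in self.contigs.items():
            if not cid:
                raise FormatError("empty contig id")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"contig {cid!r}: illegal characters {sorted(bad)}"
                )
        if self.total_length == 0:
            raise FormatError("genome has zero total length")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}


def read_genome(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`, uppercasing sequences."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {rec.id!r}: illegal characters {sorted(bad)}"
            )
        contigs[rec.id] = seq
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(contigs)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: ordered CDS segments on one contig.

    ``cds_segments`` are 0-based half-open intervals listed in transcription
    order: ascending for '+' genes, descending for '-' genes.  ``complete``
    means the spliced CDS begins with ATG, ends with a stop codon, has length
    divisible by three and no internal in-frame stop.
    """

    gene_id: str
    contig: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.cds_segments:
            raise ValueError(f"gene {self.gene_id}: no CDS segments")
        genomic = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS segments")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expect) != self.cds_segments:
            raise ValueError(
                f"gene {self.gene_id}: segments not in transcription order"
            )
        for s, e in self.cds_segments:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty CDS segment")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (min start, max end) over all CDS segments."""
        starts, ends = zip(*self.cds_segments)
        return min(starts), max(ends)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def spliced_cds(self, genome: Genome) -> str:
        """The coding sequence read 5'->3' on the coding strand."""
        seq = genome[self.contig]
        if self.strand == "+":
            return "".join(seq[s:e] for s, e in self.cds_segments)
        return "".join(revcomp(seq[s:e]) for s, e in self.cds_segments)

    def cds_offset(self, position: int) -> Optional[int]:
        """Map a genomic position to its 0-based offset in the spliced CDS.

        Returns None when the position is not inside any CDS segment.
        """
        off = 0
        for s, e in self.cds_segments:
            if s <= position < e:
                if self.strand == "+":
                    return off + (position - s)
                return off + (e - 1 - position)
            off += e - s
        return None

    def contains(self, position: int) -> bool:
        s, e = self.span
        return s <= position < e

    def in_cds(self, position: int) -> bool:
        return self.cds_offset(position) is not None


def evaluate_completeness(gene: GeneModel, genome: Genome) -> bool:
    """Check start codon, terminal stop, frame and absence of internal stops."""
    cds = gene.spliced_cds(genome)
    if len(cds) % 3 or len(cds) < 6:
        return False
    if not cds.startswith("ATG"):
        return False
    protein = translate_cds(cds)
    return protein.endswith("*") and "*" not in protein[:-1]


def read_gene_models(path: str | Path, genome: Genome) -> list[GeneModel]:
    """Read CDS features from a GFF3 file, grouped by their parent gene.

    Coordinates are converted from GFF's 1-based inclusive convention to the
    internal 0-based half-open one.  Completeness is evaluated against the
    genome rather than trusted from attributes.
    """
    by_gene: dict[str, list[tuple[str, str, int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "CDS":
                continue
            parent = None
            for item in attrs.split(";"):
                key, _, value = item.partition("=")
                if key.strip() in ("Parent", "ID") and parent is None:
                    parent = value.strip()
                if key.strip() == "Parent":
                    parent = value.strip()
            if parent is None:
                raise FormatError(f"{path}:{lineno}: CDS without Parent/ID")
            if parent not in by_gene:
                order.append(parent)
            by_gene.setdefault(parent, []).append(
                (seqid, strand, int(start) - 1, int(end))
            )
    models = []
    for gid in order:
        rows = by_gene[gid]
        contigs = {r[0] for r in rows}
        strands = {r[1] for r in rows}
        if len(contigs) > 1 or len(strands) > 1:
            raise FormatError(f"gene {gid}: inconsistent contig/strand across CDS")
        contig, strand = rows[0][0], rows[0][1]
        if contig not in genome.contigs:
            raise FormatError(f"gene {gid}: unknown contig {contig!r}")
        clen = len(genome[contig])
        segs = sorted((s, e) for _, _, s, e in rows)
        for s, e in segs:
            if s < 0 or e > clen:
                raise FormatError(f"gene {gid}: CDS beyond contig bounds")
        if strand == "-":
            segs = segs[::-1]
        gene = GeneModel(gid, contig, strand, tuple(segs), complete=True)
        gene = replace(gene, complete=evaluate_completeness(gene, genome))
        models.append(gene)
    return models


def write_gene_models(genes: Iterable[GeneModel], path: str | Path,
                      source: str = "podevol") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.contig}\t{source}\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (cs, ce) in enumerate(sorted(g.cds_segments)):
                fh.write(
                    f"{g.contig}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class MaskInterval:
    """A low-complexity interval in BED convention (0-based half-open)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty mask interval {self.contig}:{self.start}-{self.end}")


def read_mask(path: str | Path) -> list[MaskInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            contig, start, end = line.split("\t")[:3]
            out.append(MaskInterval(contig, int(start), int(end)))
    return out


def write_mask(masks: Iterable[MaskInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(masks):
            fh.write(f"{m.contig}\t{m.start}\t{m.end}\n")


# ---------------------------------------------------------------------------
# Variant calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample (population x timepoint).

    Alleles are stored minimally: an SNV has single-base ref and alt, an
    insertion has empty ref, a deletion empty alt (no VCF anchor base).
    ``position`` is the 0-based position of the first affected base.
    """

    contig: str
    position: int
    ref: str
    alt: str
    sample_id: str
    coverage: int
    alt_reads: int
    frequency: float
    population_id: Optional[str] = None
    timepoint: Optional[int] = None

    FREQ_TOL = 0.02  # rounding slack between reported frequency and alt/coverage

    def __post_init__(self) -> None:
        if self.alt_reads > self.coverage:
            raise DataIntegrityError(
                f"{self.key()}: alt_reads {self.alt_reads} > coverage {self.coverage}"
            )
        if not (0.0 <= self.frequency <= 1.0):
            raise DataIntegrityError(f"{self.key()}: frequency {self.frequency}")
        if self.coverage > 0:
            implied = self.alt_reads / self.coverage
            if abs(implied - self.frequency) > self.FREQ_TOL:
                raise DataIntegrityError(
                    f"{self.key()}: frequency {self.frequency:.3f} inconsistent "
                    f"with {self.alt_reads}/{self.coverage}"
                )
        if self.ref == self.alt:
            raise DataIntegrityError(f"{self.key()}: ref == alt")
        if len(self.ref) > 1 and len(self.alt) > 1:
            raise FormatError(
                f"{self.key()}: multi-nucleotide substitution unsupported "
                "(normalize first)"
            )

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) < len(self.alt):
            return "insertion"
        return "deletion"

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))


def normalize_variant(
    position: int, ref: str, alt: str, contig_seq: Optional[str] = None
) -> tuple[int, str, str]:
    """Reduce an allele pair to its minimal left-aligned representation.

    Shared suffix then shared prefix bases are trimmed; when the contig
    sequence is supplied, indels are shifted left through repeat tracts so
    that positional filters see a representation-invariant coordinate.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        position += 1
    if contig_seq is not None and (not ref or not alt):
        moving = ref or alt  # the inserted or deleted run
        while position > 0 and moving and contig_seq[position - 1] == moving[-1]:
            moving = contig_seq[position - 1] + moving[:-1]
            position -= 1
        if ref:
            ref = moving
        else:
            alt = moving
    return position, ref, alt


#: columns of the plain-TSV variant dialect, in order
VARIANT_TSV_COLUMNS = (
    "contig", "pos_1based", "ref", "alt", "sample",
    "coverage", "alt_reads", "frequency",
)


def read_variants_tsv(
    path: str | Path,
    sample_map: Optional[Mapping[str, tuple[str, int]]] = None,
    genome: Optional[Genome] = None,
) -> list[VariantCall]:
    """Read the TSV variant dialect (1-based positions, VCF-style alleles).

    ``sample_map`` optionally maps sample ids to (population_id, timepoint).
    """
    calls = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(VARIANT_TSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            contig = row["contig"]
            seq = genome[contig] if genome is not None else None
            ref = "" if row["ref"] == "." else row["ref"]
            alt = "" if row["alt"] == "." else row["alt"]
            pos, ref, alt = normalize_variant(
                int(row["pos_1based"]) - 1, ref, alt, seq
            )
            pop, tp = (None, None)
            if sample_map is not None and row["sample"] in sample_map:
                pop, tp = sample_map[row["sample"]]
            calls.append(VariantCall(
                contig, pos, ref, alt, row["sample"],
                int(row["coverage"]), int(row["alt_reads"]),
                float(row["frequency"]), population_id=pop, timepoint=tp,
            ))
    return calls


def write_variants_tsv(calls: Iterable[VariantCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_TSV_COLUMNS)
        for c in calls:
            # re-anchor like VCF so the file round-trips through either reader
            writer.writerow([
                c.contig, c.position + 1, c.ref or ".", c.alt or ".",
                c.sample_id, c.coverage, c.alt_reads, f"{c.frequency:.4f}",
            ])


def read_variants_vcf(
    path: str | Path,
    sample_map: Optional[Mapping[str, tuple[str, int]]] = None,
    genome: Optional[Genome] = None,
) -> list[VariantCall]:
    """Read per-sample calls from a VCF 4.x file (DP/AD FORMAT fields).

    Multi-allelic records are split into biallelic calls; samples without a
    called alt at a record are skipped.
    """
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            seq = genome[rec.chrom] if genome is not None else None
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                for sname, sample in rec.samples.items():
                    gt = sample.get("GT")
                    if gt is None or alt_idx not in gt:
                        continue
                    dp = sample.get("DP")
                    ad = sample.get("AD")
                    if dp is None or ad is None:
                        raise FormatError(
                            f"{path}: sample {sname} lacks DP/AD at "
                            f"{rec.chrom}:{rec.pos}"
                        )
                    alt_reads = ad[alt_idx]
                    pos, ref_n, alt_n = normalize_variant(
                        rec.pos - 1, rec.ref, alt, seq
                    )
                    pop, tp = (None, None)
                    if sample_map is not None and sname in sample_map:
                        pop, tp = sample_map[sname]
                    calls.append(VariantCall(
                        rec.chrom, pos, ref_n, alt_n, sname,
                        int(dp), int(alt_reads),
                        alt_reads / dp if dp else 0.0,
                        population_id=pop, timepoint=tp,
                    ))
    return calls


def read_variants(
    path: str | Path,
    sample_map: Optional[Mapping[str, tuple[str, int]]] = None,
    genome: Optional[Genome] = None,
) -> list[VariantCall]:
    """Dispatch on extension: .vcf -> VCF reader, otherwise the TSV dialect."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_variants_vcf(path, sample_map, genome)
    return read_variants_tsv(path, sample_map, genome)


def write_vcf(
    calls: Sequence[VariantCall], genome: Genome, path: str | Path
) -> None:
    """Write calls as an uncompressed single-sample-per-record VCF 4.2 file."""
    samples = sorted({c.sample_id for c in calls})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for cid, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={cid},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for c in sorted(calls, key=lambda v: (v.contig, v.position, v.sample_id)):
            seq = genome[c.contig]
            if c.is_snv:
                pos1, vref, valt = c.position + 1, c.ref, c.alt
            else:
                anchor = seq[c.position - 1] if c.position > 0 else seq[c.position]
                pos1 = c.position  # anchor base position, 1-based
                vref, valt = anchor + c.ref, anchor + c.alt
                if c.position == 0:  # anchor after the event at contig start
                    pos1, vref, valt = 1, c.ref + anchor, c.alt + anchor
            cells = []
            for s in samples:
                if s == c.sample_id:
                    ref_reads = c.coverage - c.alt_reads
                    cells.append(f"1/1:{c.coverage}:{ref_reads},{c.alt_reads}")
                else:
                    cells.append("./.:.:.")
            fh.write(
                f"{c.contig}\t{pos1}\t.\t{vref}\t{valt}\t.\tPASS\t.\tGT:DP:AD\t"
                + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Trinucleotide context
# ---------------------------------------------------------------------------

def trinucleotide_context(
    genome: Genome, contig: str, position: int
) -> Optional[str]:
    """Forward-strand 3-mer centred on ``position``; None when undefined.

    Undefined at contig edges and when any base of the window is N; the
    caller decides the fallback (the permutation engine pools such mutations
    into a uniform no-context class).
    """
    seq = genome[contig]
    if position < 1 or position > len(seq) - 2:
        return None
    window = seq[position - 1 : position + 2]
    return None if "N" in window else window


# ---------------------------------------------------------------------------
# Fixation records
# ---------------------------------------------------------------------------

EFFECT_CLASSES = (
    "missense", "nonsense", "synonymous", "intronic", "intergenic",
    "frameshift", "inframe_indel", "incomplete_gene", "unaligned",
)
SNV_EFFECTS = frozenset({"missense", "nonsense", "synonymous"})
INDEL_EFFECTS = frozenset({"frameshift", "inframe_indel"})
GENELESS_EFFECTS = frozenset({"intergenic", "unaligned"})
PROTEIN_ALTERING_SNV = frozenset({"missense", "nonsense"})


@dataclass(frozen=True)
class FixationRecord:
    """A filtered, annotated, time-reconciled fixation."""

    variant: VariantCall
    population_id: str
    effect: str
    gene_id: Optional[str] = None
    codon_index: Optional[int] = None
    residue_change: Optional[tuple[str, str]] = None
    trinucleotide_context: Optional[str] = None
    first_seen_timepoint: Optional[int] = None
    validation_status: str = "verified"
    secondary_effects: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.effect in INDEL_EFFECTS and self.variant.is_snv:
            raise ValueError(f"{self.effect} effect on an SNV")
        if self.effect in SNV_EFFECTS and not self.variant.is_snv:
            raise ValueError(f"{self.effect} effect on an indel")
        if (self.gene_id is None) != (self.effect in GENELESS_EFFECTS):
            raise ValueError(
                f"gene_id={self.gene_id!r} inconsistent with effect {self.effect}"
            )
        if self.validation_status not in ("verified", "unverifiable", "time_unknown"):
            raise ValueError(f"bad validation_status {self.validation_status!r}")

    @property
    def is_protein_altering_snv(self) -> bool:
        return self.effect in PROTEIN_ALTERING_SNV

    @property
    def is_protein_altering(self) -> bool:
        return self.effect in PROTEIN_ALTERING_SNV or self.effect in INDEL_EFFECTS
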