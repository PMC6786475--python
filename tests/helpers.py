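"""Shared test utilities: stub records, a Table-1-style fixture, and an
independent rebuild-and-translate effect oracle."""
from __future__ import annotations

from Bio.Seq import Seq

from podevol.genome_model import (
    FixationRecord,
    GeneModel,
    Genome,
    VariantCall,
    revcomp,
)

TRANSITION = ("A", "G")
TRANSVERSION = ("A", "C")


def stub_call(contig="c1", position=0, ref="A", alt="G", sample="P1_p268",
              coverage=40, alt_reads=40, frequency=1.0, population=None,
              timepoint=268):
    return VariantCall(
        contig, position, ref, alt, sample, coverage, alt_reads, frequency,
        population_id=population or sample.split("_")[0], timepoint=timepoint,
    )


def make_record(population, effect, ref="A", alt="G", position=0,
                gene_id="g1", **kw):
    geneless = effect in ("intergenic", "unaligned")
    if effect in ("frameshift", "inframe_indel"):
        ref, alt = ("A" if effect == "frameshift" else "AAA"), ""
    call = stub_call(position=position, ref=ref, alt=alt,
                     population=population, sample=f"{population}_p268")
    return FixationRecord(
        variant=call, population_id=population, effect=effect,
        gene_id=None if geneless else gene_id, **kw,
    )


def table1_records():
    """FixationRecords reproducing the published per-lineage summary counts.

    Lineage A: 85 SNVs (62 transitions) + 13 indels (9 frameshifts);
    lineage B: 40 SNVs (21 transitions) + 10 indels (4 frameshifts);
    effect-class counts as tabulated.  148 fixations in total.
    """
    layout = {
        "A": dict(
            transitions=62,
            snv_effects=[("missense", 31), ("synonymous", 6), ("nonsense", 8),
                         ("intergenic", 26), ("unaligned", 9), ("intronic", 3),
                         ("incomplete_gene", 2)],
            indels=[("frameshift", 9), ("inframe_indel", 4)],
        ),
        "B": dict(
            transitions=21,
            snv_effects=[("missense", 21), ("synonymous", 7), ("nonsense", 3),
                         ("intergenic", 5), ("unaligned", 4)],
            indels=[("frameshift", 4), ("inframe_indel", 6)],
        ),
    }
    records = []
    position = 0
    for lineage, spec in layout.items():
        population = f"{lineage}1"
        n_ts = spec["transitions"]
        snv_i = 0
        for effect, n in spec["snv_effects"]:
            for _ in range(n):
                ref, alt = TRANSITION if snv_i < n_ts else TRANSVERSION
                records.append(make_record(
                    population, effect, ref=ref, alt=alt, position=position
                ))
                snv_i += 1
                position += 10
        for effect, n in spec["indels"]:
            for _ in range(n):
                records.append(make_record(population, effect,
                                           position=position))
                position += 10
    return records


# ---------------------------------------------------------------------------
# Independent effect oracle: rebuild the mutant CDS, translate, diff
# ---------------------------------------------------------------------------

def oracle_classify_snv(genome: Genome, genes, contig, position, alt):
    """Classify an SNV by full mutant-protein reconstruction.

    Independent of the codon-level classifier: applies the substitution to
    the contig, re-extracts and re-translates every overlapping gene's
    spliced CDS with Biopython, and diffs the two proteins.
    """
    hits = []
    for gene in genes:
        if gene.contig != contig or not gene.contains(position):
            continue
        if gene.cds_offset(position) is None:
            hits.append(("intronic", gene.gene_id))
            continue
        if not gene.complete:
            hits.append(("incomplete_gene", gene.gene_id))
            continue
        seq = genome[contig]
        mutant = seq[:position] + alt + seq[position + 1 :]
        ref_protein = _translate_gene(gene, seq)
        alt_protein = _translate_gene(gene, mutant)
        if alt_protein == ref_protein:
            hits.append(("synonymous", gene.gene_id))
            continue
        diff = next(
            i for i, (a, b) in enumerate(zip(ref_protein, alt_protein))
            if a != b
        )
        effect = "nonsense" if alt_protein[diff] == "*" else "missense"
        hits.append((effect, gene.gene_id))
    if not hits:
        return ("intergenic", None)
    order = {"nonsense": 0, "missense": 2, "synonymous": 4,
             "incomplete_gene": 5, "intronic": 6}
    return min(hits, key=lambda h: order[h[0]])


def _translate_gene(gene: GeneModel, contig_seq: str) -> str:
    if gene.strand == "+":
        cds = "".join(contig_seq[s:e] for s, e in gene.cds_segments)
    else:
        cds = "".join(revcomp(contig_seq[s:e]) for s, e in gene.cds_segments)
    return str(Seq(cds).translate())


def neutral_dnds_ratio(experiment, effect_lookup, seed=12345, n=1000):
    """dN/dS from SNVs placed uniformly over the coding positions.

    Placement is uniform over CDS positions with a uniform alternative base,
    matching the equal-rates site-counting expectation, so the ratio should
    approach 1.
    """
    import numpy as np

    from podevol.effect_annotation import CODE_MISSENSE, CODE_NONSENSE
    from podevol.evo_summary import cds_site_counts

    complete = [g for g in experiment.gene_models if g.complete]
    coding_positions = []
    for g in complete:
        base = effect_lookup.offsets[g.contig]
        for s, e in g.cds_segments:
            coding_positions.extend(range(base + s, base + e))
    coding_positions = np.array(coding_positions)
    rng = np.random.default_rng(seed)
    pos = rng.choice(coding_positions, size=n)
    alt_idx = rng.integers(4, size=n)
    codes = effect_lookup.effect[pos, alt_idx]
    genes_at = effect_lookup.gene_index[pos, alt_idx]
    while (genes_at < 0).any():  # redraw alts equal to the reference base
        bad = genes_at < 0
        alt_idx[bad] = rng.integers(4, size=int(bad.sum()))
        codes = effect_lookup.effect[pos, alt_idx]
        genes_at = effect_lookup.gene_index[pos, alt_idx]
    obs_n = int(((codes == CODE_MISSENSE) | (codes == CODE_NONSENSE)).sum())
    obs_s = n - obs_n
    sites_n, sites_s = cds_site_counts(complete, experiment.genome)
    return (obs_n / sites_n) / (obs_s / sites_s)


def mirror_genome(genome: Genome, genes):
    """Reverse-complement every contig and mirror gene models and strands."""
    contigs = {c: revcomp(s) for c, s in genome.contigs.items()}
    mirrored = []
    for g in genes:
        L = len(genome[g.contig])
        segs = tuple((L - e, L - s) for s, e in g.cds_segments)
        strand = "-" if g.strand == "+" else "+"
        mirrored.append(GeneModel(g.gene_id, g.contig, strand, segs,
                                  complete=g.complete))
    return Genome(contigs), mirrored
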