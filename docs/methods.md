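# Methods

This note documents the models, conventions and numerical choices behind
`podevol`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Coordinates and variant representation

All internal coordinates are 0-based half-open on the forward strand.
GFF3 (1-based inclusive) and VCF (1-based, anchored indels) are converted
at the I/O boundary; BED is consumed unchanged. Indels are stored
minimally — an insertion has an empty reference allele, a deletion an empty
alternate — and are left-aligned through repeat tracts against the genome
before any positional filter runs, so mask-proximity and adjacency
decisions do not depend on the caller's representation. Multi-nucleotide
substitutions are rejected rather than guessed at; multi-allelic VCF rows
are split into biallelic calls.

## Filtering model

Five exclusion rules run in a fixed order: quality (coverage ≥ 10 reads
and frequency ≥ 80%, both inclusive), founder support (≥ 2 reads carrying
the allele in that lineage's founder genotype), multi-population sharing
(≥ 2 supporting reads in more than one population *and* zero founder
coverage at the site — founder-covered shared sites are kept, since
repeated fixation at a covered site is genuine parallelism), mask
proximity (indels within 10 bp of a masked interval; SNVs are exempt), and
adjacency (same-population SNV pairs ≤ 1 bp apart, both members removed).
Each rule's predicate depends only on the raw input, never on another
rule's outcome, so the surviving set is order-independent; the order
matters only for the audit trail, which attributes each removed call to
the first rule that rejected it. "Supported by two reads" is interpreted
as alt-allele-supporting reads — depth alone cannot support a variant.
The frequency threshold is applied per sample; whether it should instead
hold at every observed timepoint is left as a caller decision upstream.

Timepoint reconciliation assumes monotone fixation: a mutation confirmed
by targeted validation at any timepoint is treated as present from its
first confirmation onward. Mutations confirmed nowhere are excluded from
all statistics; mutations confirmed only at the final timepoint whose
earlier assays failed outright are kept in totals but excluded from the
accumulation regression, because their appearance time cannot be ordered.
A sequencing presence pattern that loses a mutation after it appeared
triggers a warning rather than an error.

## Effect annotation

SNVs inside the CDS of a complete gene are classified by translating the
affected codon before and after the change on the coding strand. Two
boundary conventions: a substitution in the terminal stop codon that
preserves a stop is synonymous, and a stop-loss there is missense (the
category system has no stop-loss class; missense is the closest without
inventing one). Indels are classified by their left-aligned leftmost
affected base; length modulo 3 separates frameshift from in-frame.
Variants hitting overlapping genes are classified against each and
reported under the most severe class (nonsense > frameshift > missense >
in-frame indel > synonymous > intronic), with the remainder kept as
secondary effects. Genes whose spliced CDS lacks a proper start, stop, or
intact frame are `incomplete_gene`; regions flagged as lacking annotation
liftover are passed through as `unaligned`.

## Permutation null

Observed SNVs are re-thrown onto the genome with trinucleotide-context
matching: each mutation lands uniformly on a position whose forward-strand
3-mer equals the mutation's own context, and keeps its substituted base.
Contexts are not collapsed to pyrimidine-centred equivalence classes by
default (`collapse_strand` provides the symmetrized alternative).
Placement is over the whole genome, coding and noncoding alike, with
replacement across mutations — collisions are allowed and at genome scale
negligible, which the exact-enumeration test confirms either way.
Mutations with undefined context (contig edge, N in the window) or a
context absent from the genome fall back to a uniform draw over all
eligible positions, so every replicate places exactly the observed number
of mutations. The empirical p is the inclusive right tail
(#replicates ≥ observed)/n; the add-one (r+1)/(n+1) estimator is available
behind a flag. Replicates are drawn in blocks of 500 with seeds spawned
from one root seed, which makes results independent of how the blocks are
scheduled (thread-count invariant). Alt-base preservation during
re-throwing is an assumption: the alternative of re-drawing from the
observed spectrum is not implemented.

The parallelism statistic counts genes with ≥ 2 protein-altering
single-nucleotide changes, pooling lineage-specific placements through the
shared gene-id namespace. Frameshift-driven parallelism therefore shows up
in the per-gene fixation counts but deliberately not in the
permutation-compared statistic, which is SNV-based.

## Conservation statistics

Gap fraction is the fraction of alignment columns in which either sequence
is gapped; reliability (≤ 20%) is boundary-inclusive. The conserved
fraction uses focal-residue columns as the denominator (not all columns),
so mutated-site lookups and the genome-wide background live on the same
column universe. The enrichment tests are exact binomial tests, two-sided
by default (the convention of R's `binom.test`), with the plain right tail
available via `alternative="greater"`.

Miyata's amino-acid distance is recomputed from the side-chain polarity
and volume constants (Grantham's values, which the original distance was
built on), normalized by the standard deviation of each property over the
20 residues: d(a,b) = √((Δp/σ_p)² + (Δv/σ_v)²). The matrix is validated
in-tests against an independent recomputation plus structural properties
(symmetry, zero diagonal, conservative pairs such as Leu/Ile and Asp/Glu
below the median, radical pairs such as Gly/Trp above it). The
experimental-vs-divergence comparison uses the pooled-variance two-sample
t-test (Welch behind a flag); two zero-variance groups with equal means
report p = 1 by convention.

## dN/dS

Site counting follows the equal-rates enumeration: each coding position
contributes weight syn/3 to synonymous sites (syn = number of its three
substitutions that leave the protein unchanged; stop→stop counts as
synonymous, stop gain or loss as nonsynonymous), so sites_N + sites_S
equals the CDS length exactly. dN/dS = (N/sites_N)/(S/sites_S) with N =
missense + nonsense and S = synonymous counts; the accompanying binomial
test compares N among N+S with the neutral fraction
sites_N/(sites_N+sites_S). A transition/transversion-weighted site variant
is available behind the `tstv` parameter. Zero synonymous changes give an
infinite ratio with a flag rather than an exception.

## Accumulation, passages per fixation, mutator check

The regression response is the per-interval fixation *rate* (new fixations
divided by passages in the interval, the first interval starting at
passage 0), pooled across populations and regressed by OLS on the interval
midpoint — only a rate response can exhibit a declining fixation rate when
the timepoint spacing is uneven. Passages-per-fixation is population ×
passages divided by total fixations, reported raw and rounded half-up.
The mutator check is a two-way fixed-effects ANOVA of per-timepoint counts
with lineage and population-nested-in-lineage factors; identical counts
everywhere (zero residual variance) return p = 1 for both factors by
convention. Percentages in reports round half-up: effect-class shares to
one decimal, transition shares to whole percent.

## The synthetic generator

The generator emulates the analyzed study design: eight clonal populations
(five from lineage A, three from B) sampled at passages 75/130/200/268,
fixations arising per population as a Poisson process over passages and
persisting at all later timepoints (monotone by construction). Defaults
are the study's conditions where stated: ~148 fixations expected in total
(background rate (148−23)/(8·268) per passage plus 23 planted
parallel-target hits), 125/148 of fixations SNVs, 63/125 of SNVs
protein-altering and 13/125 synonymous, a 2:1 transition:transversion
ratio (between the two lineages' observed 73% and 53% transition shares),
reliable-ortholog fraction 4,713/10,230 and conserved-column fraction 0.62
in the simulated ortholog alignments. Six parallel-target genes mirror the
study's repeatedly hit proteins, including one gene frameshifted in six
populations and one missense-hit in seven.

The founder genome is scaled down to 3 Mb with ~330 genes (~10% coding)
while mutation counts stay at the real experiment's scale. The scale was
chosen so that the expected number of *chance* parallel hits per
permutation replicate — proportional to n_mutations × mean gene length /
genome length — remains in the same regime as the real ~35 Mb genome;
matching the real coding density at a small genome size would flood the
parallelism null with birthday collisions that the full-size genome does
not have. Both lineages share one founder sequence: the analyses read each
lineage's own reference, and founder sequence divergence would add nothing
they consume.

Planted artifacts carry exactly the evidence pattern their designated
filter keys on (coverage < 10; ≥ 2 founder alt reads; two-population
sharing at a founder-uncovered site; an indel inside a mask; an adjacent
SNV pair), and true fixations are placed to avoid every filter (founder
coverage defaults to 40 reads with zero alt support, ≥ 3 bp spacing within
a population, indels clear of the mask flank), so the end-to-end recovery
tests can demand exact sensitivity and specificity.

What the generator does not emulate: within-population dynamics (no
Wright–Fisher or Moran sampling, no clonal interference, no
low-to-intermediate-frequency variants), read-level noise (no FASTQ),
mutational hotspots or context-dependent rates beyond the ts:tv ratio,
radicality bias in planted missense changes, and indel blocks or rate
heterogeneity along ortholog alignments. Passing tests therefore
demonstrate the correctness of the analysis machinery on a faithful
*fixation-level* model of the experiment, not robustness to raw-read
noise or to demographic complications.

## Problem sizes in tests

The shared test fixture uses the default 3 Mb genome; permutation checks
run 10,000 replicates (50,000 for the exact-enumeration comparison on a
38 bp toy genome, where the Monte Carlo tail must match exhaustive
enumeration within three binomial standard errors). The neutral dN/dS
calibration places 1,000 uniform coding SNVs; the ANOVA type-I-error
calibration uses 100 simulated null datasets. All seeds are fixed in the
tests.
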