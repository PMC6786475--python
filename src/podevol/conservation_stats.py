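"""Protein conservation from pairwise ortholog alignments, and the
enrichment tests built on it.

A focal proteome is compared with an outgroup proteome through pairwise
protein alignments.  An alignment is *reliable* when at most 20% of its
columns contain a gap; a column is *conserved* when both sequences carry the
identical residue.  Two binomial enrichment questions are asked: do proteins
carrying nonsense/missense fixations preferentially have reliable orthologs,
and do missense changes preferentially strike conserved sites?  Radicality
of amino-acid replacements is measured by Miyata's physicochemical distance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from scipy import stats

GAP = "-"

# Side-chain polarity and volume per residue (Grantham 1974, the constants
# behind Miyata's 1979 distance).  Distances are normalized by the standard
# deviation of each property over the 20 residues.
AA_POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}
AA_VOLUME = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
}
AMINO_ACIDS = tuple(sorted(AA_POLARITY))


class MiyataTable:
    """20x20 amino-acid distance matrix from polarity and volume.

    d(a, b) = sqrt((dp / sd_p)^2 + (dv / sd_v)^2) where sd_p and sd_v are the
    standard deviations of the respective property over the 20 residues.
    """

    def __init__(self) -> None:
        p = np.array([AA_POLARITY[a] for a in AMINO_ACIDS])
        v = np.array([AA_VOLUME[a] for a in AMINO_ACIDS])
        self.sd_polarity = float(p.std())
        self.sd_volume = float(v.std())
        dp = (p[:, None] - p[None, :]) / self.sd_polarity
        dv = (v[:, None] - v[None, :]) / self.sd_volume
        self.matrix = np.sqrt(dp ** 2 + dv ** 2)
        self._index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    def distance(self, a: str, b: str) -> float:
        try:
            return float(self.matrix[self._index[a.upper()], self._index[b.upper()]])
        except KeyError as exc:
            raise KeyError(f"not a standard amino acid: {exc}") from None


_DEFAULT_TABLE: Optional[MiyataTable] = None


def miyata_distance(a: str, b: str, table: Optional[MiyataTable] = None) -> float:
    global _DEFAULT_TABLE
    if table is None:
        if _DEFAULT_TABLE is None:
            _DEFAULT_TABLE = MiyataTable()
        table = _DEFAULT_TABLE
    return table.distance(a, b)


# ---------------------------------------------------------------------------
# Ortholog pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologPair:
    """A gapped pairwise protein alignment (focal sequence first)."""

    focal_id: str
    ortholog_id: str
    focal_aligned: str
    ortholog_aligned: str
    max_gap_fraction: float = 0.20

    def __post_init__(self) -> None:
        if len(self.focal_aligned) != len(self.ortholog_aligned):
            raise ValueError(
                f"{self.focal_id}/{self.ortholog_id}: aligned lengths differ"
            )
        if not self.focal_aligned:
            raise ValueError("empty alignment")

    @property
    def n_columns(self) -> int:
        return len(self.focal_aligned)

    @property
    def gap_fraction(self) -> float:
        """Fraction of columns in which either sequence has a gap."""
        gapped = sum(
            1 for a, b in zip(self.focal_aligned, self.ortholog_aligned)
            if a == GAP or b == GAP
        )
        return gapped / self.n_columns

    @property
    def reliable(self) -> bool:
        return self.gap_fraction <= self.max_gap_fraction

    def column_of_residue(self, focal_residue_index: int) -> int:
        """Alignment column holding the focal sequence's i-th residue (0-based)."""
        seen = -1
        for col, ch in enumerate(self.focal_aligned):
            if ch != GAP:
                seen += 1
                if seen == focal_residue_index:
                    return col
        raise IndexError(
            f"{self.focal_id}: residue index {focal_residue_index} beyond "
            f"sequence of length {seen + 1}"
        )


def conserved_fraction(pair: OrthologPair) -> float:
    """Fraction of focal-residue columns where both sequences agree.

    Columns in which the focal sequence is gapped do not enter the
    denominator; a column with a gap in either sequence is never conserved.
    """
    focal_cols = 0
    conserved = 0
    for a, b in zip(pair.focal_aligned, pair.ortholog_aligned):
        if a == GAP:
            continue
        focal_cols += 1
        if b == a:
            conserved += 1
    if focal_cols == 0:
        return 0.0
    return conserved / focal_cols


def site_is_conserved(pair: OrthologPair, focal_residue_index: int) -> bool:
    col = pair.column_of_residue(focal_residue_index)
    a, b = pair.focal_aligned[col], pair.ortholog_aligned[col]
    return a != GAP and a == b


def read_ortholog_pair(path: str | Path) -> OrthologPair:
    """Read one aligned-FASTA file holding exactly two records (focal first)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected 2 aligned records, got {len(records)}")
    return OrthologPair(
        records[0].id, records[1].id,
        str(records[0].seq).upper(), str(records[1].seq).upper(),
    )


def read_ortholog_pairs_tsv(path: str | Path) -> list[OrthologPair]:
    """Read a TSV of gapped pairs: focal_id, ortholog_id, focal_seq, orth_seq."""
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            fid, oid, fseq, oseq = line.rstrip("\n").split("\t")
            pairs.append(OrthologPair(fid, oid, fseq.upper(), oseq.upper()))
    return pairs


def write_ortholog_pairs_tsv(pairs: Iterable[OrthologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("focal_id\tortholog_id\tfocal_aligned\tortholog_aligned\n")
        for p in pairs:
            fh.write(f"{p.focal_id}\t{p.ortholog_id}\t{p.focal_aligned}\t"
                     f"{p.ortholog_aligned}\n")


# ---------------------------------------------------------------------------
# Enrichment tests
# ---------------------------------------------------------------------------

def binomial_enrichment(
    k: int, n: int, background_fraction: float, alternative: str = "two-sided"
) -> float:
    """Exact binomial test of k successes in n at the background fraction.

    The default is the two-sided exact test (the convention of R's
    binom.test); ``alternative="greater"`` gives the plain right tail
    P(X >= k).
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 < background_fraction < 1.0:
        raise ValueError("background_fraction must be in (0, 1)")
    return float(
        stats.binomtest(k, n, background_fraction, alternative=alternative).pvalue
    )


def ortholog_enrichment_test(
    k_with_ortholog: int, n_proteins: int, background_fraction: float,
    alternative: str = "two-sided",
) -> float:
    """Are mutation-carrying proteins enriched for reliable orthologs?"""
    return binomial_enrichment(
        k_with_ortholog, n_proteins, background_fraction, alternative
    )


def site_conservation_test(
    k_conserved: int, n_mutated: int, background_fraction: float,
    alternative: str = "two-sided",
) -> float:
    """Do replaced residues preferentially occupy conserved alignment columns?"""
    return binomial_enrichment(
        k_conserved, n_mutated, background_fraction, alternative
    )


def background_ortholog_fraction(
    n_reliable: int, n_complete: int
) -> float:
    """Genome-wide fraction of complete proteins with a reliable ortholog."""
    if n_complete <= 0:
        raise ValueError("no complete proteins")
    return n_reliable / n_complete


# ---------------------------------------------------------------------------
# Radicality of replacements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MiyataComparison:
    mean_experimental: float
    mean_divergence: float
    t_statistic: Optional[float]
    p_value: Optional[float]
    n_experimental: int
    n_divergence: int


def compare_miyata_means(
    experimental_changes: Sequence[tuple[str, str]],
    divergence_changes: Sequence[tuple[str, str]],
    table: Optional[MiyataTable] = None,
    welch: bool = False,
) -> MiyataComparison:
    """Compare mean Miyata distances of two sets of residue replacements.

    Uses the two-sample two-tailed Student t-test with pooled variance
    (Welch's correction behind the ``welch`` flag).  With fewer than two
    values in a group the test is undefined and only means are reported;
    two zero-variance groups with equal means give p = 1 by convention.
    """
    if not experimental_changes or not divergence_changes:
        raise ValueError("both replacement lists must be nonempty")
    x = np.array([miyata_distance(a, b, table) for a, b in experimental_changes])
    y = np.array([miyata_distance(a, b, table) for a, b in divergence_changes])
    mx, my = float(x.mean()), float(y.mean())
    if len(x) < 2 or len(y) < 2:
        return MiyataComparison(mx, my, None, None, len(x), len(y))
    if x.std() == 0 and y.std() == 0:
        p = 1.0 if math.isclose(mx, my) else 0.0
        return MiyataComparison(mx, my, None, p, len(x), len(y))
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return MiyataComparison(mx, my, float(t), float(p), len(x), len(y))
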