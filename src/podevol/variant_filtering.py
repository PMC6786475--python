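"""Exclusion filters that reduce raw per-sample calls to candidate fixations.

The composite filter applies, in a fixed order: quality (coverage and
frequency thresholds), founder support, multi-population sharing, mask
proximity (indels only) and same-population adjacency.  Each rule's
predicate depends only on the raw input, so the surviving set is
order-independent; the order only affects which rule an excluded call is
attributed to in the audit trail.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .genome_model import MaskInterval, VariantCall


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the exclusion rules.

    Defaults follow the study conditions: calls need >=10 reads and >=80%
    frequency; a variant is ancestral when >=2 founder reads support it;
    indels within 10 bp of a low-complexity mask are dropped; SNV pairs at
    adjacent sites in one population are dropped as dinucleotide events.
    """

    min_coverage: int = 10
    min_frequency: float = 0.80
    founder_support_reads: int = 2
    multi_population_support_reads: int = 2
    mask_flank: int = 10
    adjacency_distance: int = 1

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_frequency", "founder_support_reads",
                     "multi_population_support_reads", "mask_flank",
                     "adjacency_distance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


RULE_ORDER = ("quality", "founder", "multi_population", "mask", "adjacency")


@dataclass
class FilterReport:
    """Survivors plus a per-call audit trail of which rule removed what."""

    survivors: list[VariantCall] = field(default_factory=list)
    removed: dict[str, list[VariantCall]] = field(
        default_factory=lambda: {r: [] for r in RULE_ORDER}
    )
    warnings: list[str] = field(default_factory=list)

    @property
    def removal_counts(self) -> dict[str, int]:
        return {rule: len(calls) for rule, calls in self.removed.items()}

    @property
    def n_input(self) -> int:
        return len(self.survivors) + sum(len(v) for v in self.removed.values())

    def rule_removing(self, call: VariantCall) -> Optional[str]:
        for rule, calls in self.removed.items():
            if call in calls:
                return rule
        return None


class FounderEvidence:
    """Read support in a founder genotype, per lineage.

    Sites not explicitly recorded default to ``default_coverage`` reads with
    zero alt support (a well-covered founder without the variant).
    """

    def __init__(self, default_coverage: int = 40):
        self.default_coverage = default_coverage
        self._sites: dict[tuple[str, str, int, str], tuple[int, int]] = {}

    def set(self, lineage: str, contig: str, position: int, alt: str,
            coverage: int, alt_reads: int) -> None:
        self._sites[(lineage, contig, position, alt)] = (coverage, alt_reads)

    def get(self, lineage: str, contig: str, position: int, alt: str
            ) -> tuple[int, int]:
        return self._sites.get(
            (lineage, contig, position, alt), (self.default_coverage, 0)
        )

    def items(self):
        return self._sites.items()


def lineage_of(call: VariantCall) -> str:
    """Founder lineage of a call: first character of its population id."""
    pop = call.population_id or call.sample_id
    return pop[0]


def apply_quality_filter(
    calls: Iterable[VariantCall], config: FilterConfig
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Keep calls with coverage and frequency at or above threshold."""
    kept, removed = [], []
    for c in calls:
        ok = c.coverage >= config.min_coverage and c.frequency >= config.min_frequency
        (kept if ok else removed).append(c)
    return kept, removed


def apply_founder_filter(
    calls: Iterable[VariantCall],
    founder: FounderEvidence,
    config: FilterConfig,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Drop calls whose allele is supported by founder reads (ancestral)."""
    kept, removed = [], []
    for c in calls:
        _, alt_reads = founder.get(lineage_of(c), c.contig, c.position, c.alt)
        if alt_reads >= config.founder_support_reads:
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def apply_multipopulation_filter(
    calls: Sequence[VariantCall],
    founder: FounderEvidence,
    config: FilterConfig,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Drop alleles shared by several populations at founder-uncovered sites.

    An allele is removed everywhere when at least two populations support it
    with >= ``multi_population_support_reads`` alt reads while the founder
    has zero coverage at the site; founder-covered sites are untouched even
    if shared (such repeated fixations are genuine parallelism).
    """
    support: dict[tuple[str, int, str], set[str]] = defaultdict(set)
    for c in calls:
        if c.alt_reads >= config.multi_population_support_reads:
            support[(c.contig, c.position, c.alt)].add(
                c.population_id or c.sample_id
            )
    kept, removed = [], []
    for c in calls:
        pops = support.get((c.contig, c.position, c.alt), set())
        coverage, _ = founder.get(lineage_of(c), c.contig, c.position, c.alt)
        if len(pops) > 1 and coverage == 0:
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def apply_mask_filter(
    calls: Iterable[VariantCall],
    masks: Sequence[MaskInterval],
    config: FilterConfig,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Drop indels within ``mask_flank`` bp of a masked interval (inclusive).

    SNVs are never removed by this rule.
    """
    by_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for m in masks:
        by_contig[m.contig].append(
            (m.start - config.mask_flank, m.end + config.mask_flank)
        )
    kept, removed = [], []
    for c in calls:
        if c.is_snv:
            kept.append(c)
            continue
        hit = any(s <= c.position < e for s, e in by_contig.get(c.contig, ()))
        (removed if hit else kept).append(c)
    return kept, removed


def apply_adjacency_filter(
    calls: Sequence[VariantCall], config: FilterConfig
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Drop same-population SNV pairs at adjacent sites (both members).

    Within one population, two SNVs on the same contig at distance
    <= ``adjacency_distance`` are treated as one dinucleotide mutation
    event and excluded.
    """
    snv_positions: dict[tuple[str, str], set[int]] = defaultdict(set)
    for c in calls:
        if c.is_snv:
            snv_positions[(c.population_id or c.sample_id, c.contig)].add(c.position)
    kept, removed = [], []
    for c in calls:
        if not c.is_snv:
            kept.append(c)
            continue
        positions = snv_positions[(c.population_id or c.sample_id, c.contig)]
        adjacent = any(
            d != 0 and (c.position + d) in positions
            for d in range(-config.adjacency_distance, config.adjacency_distance + 1)
        )
        (removed if adjacent else kept).append(c)
    return kept, removed


def apply_filters(
    calls: Sequence[VariantCall],
    founder: FounderEvidence,
    masks: Sequence[MaskInterval],
    config: Optional[FilterConfig] = None,
) -> FilterReport:
    """Run all exclusion rules in the fixed order and return the audit trail."""
    config = config or FilterConfig()
    report = FilterReport()
    surviving = list(calls)
    surviving, report.removed["quality"] = apply_quality_filter(surviving, config)
    surviving, report.removed["founder"] = apply_founder_filter(
        surviving, founder, config
    )
    surviving, report.removed["multi_population"] = apply_multipopulation_filter(
        surviving, founder, config
    )
    surviving, report.removed["mask"] = apply_mask_filter(surviving, masks, config)
    surviving, report.removed["adjacency"] = apply_adjacency_filter(surviving, config)
    report.survivors = surviving
    return report


# ---------------------------------------------------------------------------
# Timepoint reconciliation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReconciledMutation:
    """Validation outcome for one candidate fixation across timepoints."""

    mutation_key: tuple
    validation_status: str  # verified | unverifiable | time_unknown
    first_seen_timepoint: Optional[int]
    imputed_presence: tuple[int, ...]  # timepoints at which the mutation is present


def reconcile_timepoints(
    ngs_presence: Mapping[tuple, Mapping[int, bool]],
    validation: Mapping[tuple, Mapping[int, Optional[bool]]],
    timepoints: Sequence[int],
) -> tuple[list[ReconciledMutation], list[str]]:
    """Reconcile sequencing presence with targeted (Sanger-style) validation.

    A mutation is *verified* when confirmed at any timepoint; presence is
    then imputed as monotone from the first confirmation onward (a mutation
    that appeared once is assumed fixed at later timepoints).  Mutations
    confirmed nowhere are *unverifiable* and are excluded from downstream
    statistics.  Mutations confirmed only at the final timepoint whose
    earlier assays all failed (None) are *time_unknown*: they count toward
    totals but not toward the accumulation regression.

    Returns the reconciled records and a list of monotonicity warnings for
    sequencing presence patterns showing a loss after an appearance.
    """
    timepoints = sorted(timepoints)
    results: list[ReconciledMutation] = []
    warnings: list[str] = []
    for key in validation:
        val = validation[key]
        ngs = ngs_presence.get(key, {})
        seen = [t for t in timepoints if ngs.get(t)]
        if seen:
            first_ngs = seen[0]
            lost = [t for t in timepoints if t > first_ngs and ngs.get(t) is False]
            if lost:
                warnings.append(
                    f"{key}: present at {first_ngs} but absent at {lost} in "
                    "sequencing data (non-monotone trajectory)"
                )
        confirmed = [t for t in timepoints if val.get(t) is True]
        if not confirmed:
            results.append(ReconciledMutation(key, "unverifiable", None, ()))
            continue
        first = confirmed[0]
        earlier = [t for t in timepoints if t < first]
        if first == timepoints[-1] and earlier and all(
            val.get(t) is None for t in earlier
        ):
            status = "time_unknown"
            first_seen = None
            presence = (timepoints[-1],)
        else:
            status = "verified"
            first_seen = first
            presence = tuple(t for t in timepoints if t >= first)
        results.append(ReconciledMutation(key, status, first_seen, presence))
    return results, warnings
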