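"""Fixation summary tables and headline evolutionary statistics.

Covers the per-lineage tabulation by mutation type and effect class,
transition/transversion shares, a site-counting dN/dS with a binomial test
against the neutral expectation, the fixation-accumulation regression, the
passages-per-fixation summary and a two-way ANOVA mutator check.
"""
from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (
    CODON_TABLE,
    FixationRecord,
    GeneModel,
    Genome,
)

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in TRANSITIONS


def round_half_up(x: float, digits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    factor = 10 ** digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Fixation summary
# ---------------------------------------------------------------------------

@dataclass
class FixationSummary:
    """Per-lineage counts by mutation type and effect class, with shares."""

    per_lineage_effects: dict[str, Counter] = field(default_factory=dict)
    per_lineage_transitions: dict[str, int] = field(default_factory=dict)
    per_lineage_transversions: dict[str, int] = field(default_factory=dict)
    per_lineage_snvs: dict[str, int] = field(default_factory=dict)
    per_lineage_indels: dict[str, int] = field(default_factory=dict)
    per_lineage_totals: dict[str, int] = field(default_factory=dict)

    @property
    def total_fixations(self) -> int:
        return sum(self.per_lineage_totals.values())

    @property
    def total_snvs(self) -> int:
        return sum(self.per_lineage_snvs.values())

    def effect_total(self, effect: str) -> int:
        return sum(c.get(effect, 0) for c in self.per_lineage_effects.values())

    def share_percent(self, effect: str) -> Optional[float]:
        """Percentage of all fixations in an effect class, to one decimal."""
        if self.total_fixations == 0:
            return None
        return round_half_up(
            100.0 * self.effect_total(effect) / self.total_fixations, 1
        )

    def transition_share_percent(self, lineage: str) -> Optional[int]:
        """Transitions as a whole-percent share of a lineage's SNVs."""
        snvs = self.per_lineage_snvs.get(lineage, 0)
        if snvs == 0:
            return None
        return int(round_half_up(
            100.0 * self.per_lineage_transitions[lineage] / snvs
        ))

    def to_frame(self) -> pd.DataFrame:
        lineages = sorted(self.per_lineage_totals)
        rows = {}
        rows["total"] = [self.per_lineage_totals[l] for l in lineages]
        rows["transition"] = [self.per_lineage_transitions[l] for l in lineages]
        rows["transversion"] = [self.per_lineage_transversions[l] for l in lineages]
        for eff in ("missense", "synonymous", "nonsense", "intergenic",
                    "unaligned", "intronic", "incomplete_gene", "frameshift",
                    "inframe_indel"):
            rows[eff] = [
                self.per_lineage_effects[l].get(eff, 0) for l in lineages
            ]
        rows["indels"] = [self.per_lineage_indels[l] for l in lineages]
        return pd.DataFrame(rows, index=lineages).T


def summarize_fixations(
    records: Sequence[FixationRecord],
    lineage_of=lambda pop: pop[0],
) -> FixationSummary:
    """Tabulate fixations per founder lineage.

    ``lineage_of`` maps a population id to its founder lineage; the default
    takes the leading character (populations A1..A5 -> lineage A).
    """
    s = FixationSummary()
    for rec in records:
        lin = lineage_of(rec.population_id)
        s.per_lineage_effects.setdefault(lin, Counter())
        s.per_lineage_transitions.setdefault(lin, 0)
        s.per_lineage_transversions.setdefault(lin, 0)
        s.per_lineage_snvs.setdefault(lin, 0)
        s.per_lineage_indels.setdefault(lin, 0)
        s.per_lineage_totals.setdefault(lin, 0)
        s.per_lineage_totals[lin] += 1
        s.per_lineage_effects[lin][rec.effect] += 1
        if rec.variant.is_snv:
            s.per_lineage_snvs[lin] += 1
            if is_transition(rec.variant.ref, rec.variant.alt):
                s.per_lineage_transitions[lin] += 1
            else:
                s.per_lineage_transversions[lin] += 1
        else:
            s.per_lineage_indels[lin] += 1
    return s


# ---------------------------------------------------------------------------
# dN/dS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DndsResult:
    observed_nonsyn: int
    observed_syn: int
    sites_nonsyn: float
    sites_syn: float
    ratio: float  # inf when no synonymous changes observed
    binomial_p: Optional[float]

    @property
    def infinite(self) -> bool:
        return math.isinf(self.ratio)


_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def cds_site_counts(
    genes: Sequence[GeneModel], genome: Genome, tstv: Optional[float] = None
) -> tuple[float, float]:
    """Expected nonsynonymous and synonymous site counts over a CDS set.

    Every coding position contributes total weight 1, split by the fraction
    of its three possible substitutions that leave the protein unchanged
    (stop-to-stop counts as synonymous, any residue change or stop gain/loss
    as nonsynonymous).  With ``tstv`` set, the transition substitution gets
    weight tstv and each transversion weight 1 instead of equal rates.
    """
    sites_n = sites_s = 0.0
    for gene in genes:
        if not gene.complete:
            continue
        cds = gene.spliced_cds(genome)
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            aa = CODON_TABLE[codon]
            for within in range(3):
                ref_base = codon[within]
                syn_w = tot_w = 0.0
                for b in "ACGT":
                    if b == ref_base:
                        continue
                    w = (tstv if (tstv is not None and b == _TS_PARTNER[ref_base])
                         else 1.0)
                    tot_w += w
                    new = codon[:within] + b + codon[within + 1 :]
                    if CODON_TABLE[new] == aa:
                        syn_w += w
                sites_s += syn_w / tot_w
                sites_n += 1.0 - syn_w / tot_w
    return sites_n, sites_s


def dnds(
    coding_records: Sequence[FixationRecord],
    genes: Sequence[GeneModel],
    genome: Genome,
    tstv: Optional[float] = None,
) -> DndsResult:
    """Site-counting dN/dS over observed coding SNVs.

    Nonsynonymous changes are missense plus nonsense SNVs; the binomial test
    compares the observed nonsynonymous share with the neutral expectation
    sites_N / (sites_N + sites_S).
    """
    obs_n = sum(1 for r in coding_records if r.effect in ("missense", "nonsense"))
    obs_s = sum(1 for r in coding_records if r.effect == "synonymous")
    sites_n, sites_s = cds_site_counts(genes, genome, tstv=tstv)
    if sites_n <= 0 or sites_s <= 0:
        raise ValueError("empty CDS set")
    if obs_s == 0:
        ratio = math.inf if obs_n else 0.0
    else:
        ratio = (obs_n / sites_n) / (obs_s / sites_s)
    p = None
    if obs_n + obs_s > 0:
        expected_frac = sites_n / (sites_n + sites_s)
        p = float(stats.binomtest(obs_n, obs_n + obs_s, expected_frac).pvalue)
    return DndsResult(obs_n, obs_s, sites_n, sites_s, ratio, p)


# ---------------------------------------------------------------------------
# Accumulation regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccumulationFit:
    slope: float
    intercept: float
    slope_p: float
    rates: pd.DataFrame  # population, interval midpoint, fixations per passage


def accumulation_regression(
    new_fixations: Mapping[str, Mapping[int, int]],
    passage_numbers: Sequence[int],
) -> AccumulationFit:
    """Regress the per-interval fixation rate on time.

    ``new_fixations[population][timepoint]`` counts fixations first seen at
    that timepoint.  For each population the rate over an interval is the
    new-fixation count divided by the number of passages in the interval
    (the first interval runs from passage 0); rates are pooled across
    populations and fitted by OLS against the interval midpoint.
    """
    passages = sorted(passage_numbers)
    if len(passages) < 2:
        raise ValueError("need at least two timepoints to fit a rate trend")
    bounds = [0] + passages
    rows = []
    for pop, counts in new_fixations.items():
        for lo, hi in zip(bounds, bounds[1:]):
            rows.append({
                "population": pop,
                "midpoint": (lo + hi) / 2,
                "rate": counts.get(hi, 0) / (hi - lo),
            })
    rates = pd.DataFrame(rows)
    if rates["midpoint"].nunique() < 2:
        raise ValueError("need at least two intervals to fit a rate trend")
    import statsmodels.api as sm

    x = sm.add_constant(rates["midpoint"].to_numpy())
    fit = sm.OLS(rates["rate"].to_numpy(), x).fit()
    return AccumulationFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_p=float(fit.pvalues[1]),
        rates=rates,
    )


# ---------------------------------------------------------------------------
# Passages per fixation
# ---------------------------------------------------------------------------

def passages_per_fixation(
    n_populations: int, total_passages: int, total_fixations: int
) -> tuple[float, int]:
    """Population-passages per observed fixation: raw value and rounded."""
    if total_fixations <= 0:
        raise ValueError("no fixations observed: passages per fixation undefined")
    raw = n_populations * total_passages / total_fixations
    return raw, int(round_half_up(raw))


# ---------------------------------------------------------------------------
# Mutator check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutatorTest:
    lineage_p: float
    population_p: float
    table: Optional[pd.DataFrame]


def mutator_test(
    new_fixations: Mapping[str, Mapping[int, int]],
    lineage_of=lambda pop: pop[0],
) -> MutatorTest:
    """Two-way ANOVA of per-timepoint fixation counts.

    Factors are founder lineage and population nested within lineage; the
    per-timepoint new-fixation counts are the response.  A mutator
    population shows up on the population factor; a lineage-wide rate
    difference on the lineage factor.  With zero residual variance
    (identical counts everywhere) both p-values are 1 by convention.
    """
    rows = []
    for pop, counts in new_fixations.items():
        for tp, n in sorted(counts.items()):
            rows.append({
                "lineage": lineage_of(pop), "population": pop,
                "timepoint": tp, "count": n,
            })
    df = pd.DataFrame(rows)
    if df["count"].nunique() == 1:
        return MutatorTest(1.0, 1.0, None)
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("count ~ C(lineage) / C(population)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    lineage_p = float(table.loc["C(lineage)", "PR(>F)"])
    population_p = float(table.loc["C(lineage):C(population)", "PR(>F)"])
    if math.isnan(lineage_p):
        lineage_p = 1.0
    if math.isnan(population_p):
        population_p = 1.0
    return MutatorTest(lineage_p, population_p, table)


def new_fixation_counts(
    records: Sequence[FixationRecord], timepoints: Sequence[int],
    populations: Optional[Sequence[str]] = None,
) -> dict[str, dict[int, int]]:
    """Count fixations by population and first-seen timepoint.

    Records with unknown appearance time (validation_status 'time_unknown')
    are skipped; they count toward totals but cannot be placed on the time
    axis.
    """
    pops = set(populations or ())
    counts: dict[str, dict[int, int]] = defaultdict(
        lambda: {t: 0 for t in timepoints}
    )
    for p in populations or ():
        counts[p]  # materialize empty populations
    for rec in records:
        if rec.validation_status == "time_unknown":
            continue
        if rec.first_seen_timepoint is None:
            continue
        counts[rec.population_id][rec.first_seen_timepoint] += 1
        pops.add(rec.population_id)
    return {p: dict(counts[p]) for p in sorted(pops)}
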