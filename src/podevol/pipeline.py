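"""End-to-end orchestration: filter -> reconcile -> annotate -> permute ->
conservation -> summarize, plus run-directory management and reporting.

`analyze_experiment` is the library entry point; `run_pipeline` wraps it
with file emission, checksummed manifests and derived per-stage seeds so a
run is reproducible from one global seed.
"""
from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import conservation_stats as cons
from . import evo_summary as evo
from .effect_annotation import EffectLookup, annotate_variant
from .genome_model import FixationRecord, VariantCall
from .permutation_null import (
    ContextIndex,
    ObservedSnv,
    PermutationConfig,
    PermutationResult,
    build_context_index,
    null_effect_counts,
    null_parallel_genes,
    observed_parallel_gene_count,
)
from .synthetic_data import (
    ExperimentConfig,
    SyntheticExperiment,
    generate_experiment,
    write_experiment,
)
from .variant_filtering import (
    FilterConfig,
    FilterReport,
    FounderEvidence,
    reconcile_timepoints,
)

SCHEMA_VERSION = 1


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class AnalysisResult:
    """All statistics of one pipeline run."""

    filter_report: FilterReport
    records: list[FixationRecord]
    excluded_unverifiable: list[tuple]
    summary: evo.FixationSummary
    effect_nulls: dict[str, dict[str, PermutationResult]]  # lineage -> stat
    parallel_null: Optional[PermutationResult]
    observed_parallel_snv_genes: int
    observed_parallel_genes_all: int
    conservation: dict
    dnds: Optional[evo.DndsResult]
    accumulation: Optional[evo.AccumulationFit]
    passages_per_fixation: Optional[tuple[float, int]]
    mutator: Optional[evo.MutatorTest]
    warnings: list[str] = field(default_factory=list)


def analyze_experiment(
    exp: SyntheticExperiment,
    filter_config: Optional[FilterConfig] = None,
    perm_config: Optional[PermutationConfig] = None,
    lookup: Optional[EffectLookup] = None,
    context_index: Optional[ContextIndex] = None,
    run_permutations: bool = True,
) -> AnalysisResult:
    """Run the full analysis on one (synthetic or loaded) experiment.

    ``lookup`` / ``context_index`` may be passed in when already built for
    the same genome and annotation (they are seed-independent).
    """
    from .variant_filtering import apply_filters

    fc = filter_config or FilterConfig()
    pc = perm_config or PermutationConfig()
    tps = list(exp.config.timepoints)

    report = apply_filters(exp.calls, exp.founder, exp.masks, fc)

    # group surviving calls by mutation and reconcile with validation
    by_key: dict[tuple, list[VariantCall]] = {}
    for c in report.survivors:
        key = (c.population_id or c.sample_id, c.contig, c.position, c.ref, c.alt)
        by_key.setdefault(key, []).append(c)
    presence = {
        key: {tp: any(c.timepoint == tp for c in calls) for tp in tps}
        for key, calls in by_key.items()
    }
    validation = dict(exp.validation)
    for key in by_key:
        # candidates without a validation row cannot be confirmed
        validation.setdefault(key, {tp: None for tp in tps})
    reconciled, warnings = reconcile_timepoints(presence, validation, tps)
    status = {r.mutation_key: r for r in reconciled}

    records: list[FixationRecord] = []
    excluded: list[tuple] = []
    for key, calls in sorted(by_key.items()):
        rec_status = status[key]
        if rec_status.validation_status == "unverifiable":
            excluded.append(key)
            continue
        first_call = min(calls, key=lambda c: c.timepoint or 0)
        record = annotate_variant(
            first_call, exp.gene_models, exp.genome
        )
        records.append(dataclasses.replace(
            record,
            first_seen_timepoint=rec_status.first_seen_timepoint,
            validation_status=rec_status.validation_status,
        ))

    summary = evo.summarize_fixations(records)

    # --- permutation nulls ------------------------------------------------
    effect_nulls: dict[str, dict[str, PermutationResult]] = {}
    parallel_null = None
    observed_parallel = observed_parallel_gene_count(records, snv_only=True)
    observed_parallel_all = observed_parallel_gene_count(records, snv_only=False)
    if run_permutations:
        if lookup is None:
            lookup = EffectLookup(exp.genome, exp.gene_models)
        if context_index is None:
            context_index = build_context_index(
                exp.genome, collapse_strand=pc.collapse_strand
            )
        lineages = sorted({r.population_id[0] for r in records})
        observed_sets, per_lineage_counts = [], []
        for lin in lineages:
            lin_records = [
                r for r in records
                if r.population_id.startswith(lin) and r.variant.is_snv
            ]
            observed_sets.append([ObservedSnv.from_record(r) for r in lin_records])
            per_lineage_counts.append({
                "nonsense": sum(1 for r in lin_records if r.effect == "nonsense"),
                "missense": sum(1 for r in lin_records if r.effect == "missense"),
            })
        for lin, observed, counts in zip(
            lineages, observed_sets, per_lineage_counts
        ):
            lin_pc = dataclasses.replace(
                pc, seed=stage_seed(pc.seed, f"effect_null_{lin}")
            )
            effect_nulls[lin] = null_effect_counts(
                exp.genome, lookup, context_index, observed, counts, lin_pc
            )
        par_pc = dataclasses.replace(pc, seed=stage_seed(pc.seed, "parallel"))
        parallel_null = null_parallel_genes(
            [lookup] * len(lineages), [context_index] * len(lineages),
            observed_sets, observed_parallel, par_pc,
        )

    conservation = _conservation_block(records, exp)

    coding = [r for r in records
              if r.effect in ("missense", "nonsense", "synonymous")]
    complete_genes = [g for g in exp.gene_models if g.complete]
    dnds_res = evo.dnds(coding, complete_genes, exp.genome) if coding else None

    counts = evo.new_fixation_counts(records, tps, exp.config.populations)
    accumulation = None
    mutator = None
    if counts and len(tps) >= 2:
        accumulation = evo.accumulation_regression(counts, tps)
        mutator = evo.mutator_test(counts)
    ppf = None
    if records:
        ppf = evo.passages_per_fixation(
            len(exp.config.populations), max(tps), len(records)
        )

    return AnalysisResult(
        filter_report=report,
        records=records,
        excluded_unverifiable=excluded,
        summary=summary,
        effect_nulls=effect_nulls,
        parallel_null=parallel_null,
        observed_parallel_snv_genes=observed_parallel,
        observed_parallel_genes_all=observed_parallel_all,
        conservation=conservation,
        dnds=dnds_res,
        accumulation=accumulation,
        passages_per_fixation=ppf,
        mutator=mutator,
        warnings=warnings,
    )


def _conservation_block(
    records: Sequence[FixationRecord], exp: SyntheticExperiment
) -> dict:
    """Ortholog/conservation enrichment statistics for one run."""
    pairs = {p.focal_id: p for p in exp.ortholog_pairs}
    complete = [g for g in exp.gene_models if g.complete]
    reliable = {
        pid for pid, p in pairs.items() if p.reliable
    }
    n_complete = len(complete)
    background = len(reliable) / n_complete if n_complete else 0.0

    out: dict = {
        "n_complete_proteins": n_complete,
        "n_reliable_orthologs": len(reliable),
        "background_ortholog_fraction": background,
    }
    if not (0.0 < background < 1.0):
        return out

    for effect in ("nonsense", "missense"):
        genes = sorted({
            r.gene_id for r in records
            if r.effect == effect and r.gene_id is not None
        })
        k = sum(1 for g in genes if g in reliable)
        out[f"{effect}_proteins"] = len(genes)
        out[f"{effect}_with_reliable_ortholog"] = k
        out[f"{effect}_ortholog_p"] = (
            cons.ortholog_enrichment_test(k, len(genes), background)
            if genes else None
        )

    # pooled conserved-column background over reliable alignments
    cols = conserved = 0
    for pid in reliable:
        p = pairs[pid]
        for a, b in zip(p.focal_aligned, p.ortholog_aligned):
            if a != cons.GAP:
                cols += 1
                if a == b:
                    conserved += 1
    if cols:
        bg_sites = conserved / cols
        out["background_conserved_fraction"] = bg_sites
        mutated = [
            r for r in records
            if r.effect == "missense" and r.gene_id in reliable
            and r.codon_index is not None
            # stop-loss changes sit past the aligned protein; skip them
            and r.codon_index < sum(
                1 for ch in pairs[r.gene_id].focal_aligned if ch != cons.GAP
            )
        ]
        k_cons = sum(
            1 for r in mutated
            if cons.site_is_conserved(pairs[r.gene_id], r.codon_index)
        )
        out["mutated_sites"] = len(mutated)
        out["mutated_sites_conserved"] = k_cons
        out["site_conservation_p"] = (
            cons.site_conservation_test(k_cons, len(mutated), bg_sites)
            if mutated and 0.0 < bg_sites < 1.0 else None
        )
        # radicality: experimental replacements vs between-species divergence
        experimental = [
            r.residue_change for r in records
            if r.effect == "missense" and r.residue_change is not None
            and "*" not in r.residue_change
        ]
        divergence = []
        for pid in sorted(reliable):
            p = pairs[pid]
            for a, b in zip(p.focal_aligned, p.ortholog_aligned):
                if a != cons.GAP and b != cons.GAP and a != b:
                    divergence.append((a, b))
        if len(experimental) >= 2 and len(divergence) >= 2:
            comp = cons.compare_miyata_means(experimental, divergence)
            out["miyata_mean_experimental"] = comp.mean_experimental
            out["miyata_mean_divergence"] = comp.mean_divergence
            out["miyata_t_p"] = comp.p_value
    return out


# ---------------------------------------------------------------------------
# Fixation record TSV I/O
# ---------------------------------------------------------------------------

RECORD_COLUMNS = (
    "population", "contig", "pos_1based", "ref", "alt", "variant_class",
    "effect", "gene_id", "codon_index", "residue_from", "residue_to",
    "context", "first_seen_timepoint", "validation_status",
)


def write_fixation_records(
    records: Sequence[FixationRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RECORD_COLUMNS)
        for r in records:
            v = r.variant
            w.writerow([
                r.population_id, v.contig, v.position + 1, v.ref or ".",
                v.alt or ".", v.variant_class, r.effect, r.gene_id or ".",
                "." if r.codon_index is None else r.codon_index,
                r.residue_change[0] if r.residue_change else ".",
                r.residue_change[1] if r.residue_change else ".",
                r.trinucleotide_context or ".",
                "." if r.first_seen_timepoint is None else r.first_seen_timepoint,
                r.validation_status,
            ])


# ---------------------------------------------------------------------------
# Run directory orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "run"
    experiment: ExperimentConfig = None  # type: ignore[assignment]
    filter: FilterConfig = None          # type: ignore[assignment]
    n_permutation_reps: int = 10_000
    context_matched: bool = True
    collapse_strand: bool = False

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        seed = int(raw.get("seed", 0))
        exp_kwargs = dict(raw.get("experiment", {}))
        exp_kwargs.setdefault("seed", stage_seed(seed, "generate"))
        if "parallel_targets" in exp_kwargs:
            from .synthetic_data import ParallelTarget
            exp_kwargs["parallel_targets"] = tuple(
                ParallelTarget(t["gene_rank"], t["effect"],
                               tuple(t["populations"]))
                for t in exp_kwargs["parallel_targets"]
            )
        for tuple_key in ("timepoints", "populations"):
            if tuple_key in exp_kwargs:
                exp_kwargs[tuple_key] = tuple(exp_kwargs[tuple_key])
        return cls(
            seed=seed,
            outdir=str(raw.get("outdir", "run")),
            experiment=ExperimentConfig(**exp_kwargs),
            filter=FilterConfig(**raw.get("filter", {})),
            n_permutation_reps=int(raw.get("n_permutation_reps", 10_000)),
            context_matched=bool(raw.get("context_matched", True)),
            collapse_strand=bool(raw.get("collapse_strand", False)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _result_json(result: AnalysisResult) -> dict:
    perm = {}
    for lin, nulls in result.effect_nulls.items():
        perm[lin] = {
            name: {"observed": r.observed, "p": r.p_value, "n_reps": r.n_reps}
            for name, r in nulls.items()
        }
    summary = result.summary
    out = {
        "schema_version": SCHEMA_VERSION,
        "n_fixations": summary.total_fixations,
        "n_snvs": summary.total_snvs,
        "per_lineage_snvs": dict(summary.per_lineage_snvs),
        "transition_share_percent": {
            lin: summary.transition_share_percent(lin)
            for lin in summary.per_lineage_totals
        },
        "shares_percent": {
            eff: summary.share_percent(eff)
            for eff in ("missense", "nonsense", "frameshift")
        },
        "filter_removals": result.filter_report.removal_counts,
        "n_unverifiable_excluded": len(result.excluded_unverifiable),
        "effect_nulls": perm,
        "observed_parallel_snv_genes": result.observed_parallel_snv_genes,
        "observed_parallel_genes_all": result.observed_parallel_genes_all,
        "conservation": {
            k: v for k, v in result.conservation.items()
        },
        "warnings": result.warnings,
    }
    if result.parallel_null is not None:
        out["parallel_null"] = {
            "observed": result.parallel_null.observed,
            "p": result.parallel_null.p_value,
            "n_reps": result.parallel_null.n_reps,
        }
    if result.dnds is not None:
        d = result.dnds
        out["dnds"] = {
            "observed_nonsyn": d.observed_nonsyn,
            "observed_syn": d.observed_syn,
            "sites_nonsyn": d.sites_nonsyn,
            "sites_syn": d.sites_syn,
            "ratio": None if d.infinite else d.ratio,
            "binomial_p": d.binomial_p,
        }
    if result.accumulation is not None:
        out["accumulation"] = {
            "slope": result.accumulation.slope,
            "intercept": result.accumulation.intercept,
            "slope_p": result.accumulation.slope_p,
        }
    if result.passages_per_fixation is not None:
        raw, rounded = result.passages_per_fixation
        out["passages_per_fixation"] = {"raw": raw, "rounded": rounded}
    if result.mutator is not None:
        out["mutator"] = {
            "lineage_p": result.mutator.lineage_p,
            "population_p": result.mutator.population_p,
        }
    return out


def run_pipeline(config: RunConfig, outdir: Optional[str | Path] = None) -> Path:
    """Execute generate -> analyze, writing inputs, outputs and a manifest.

    Returns the run directory.  Re-running with the same config reproduces
    every file byte-identically (the manifest stores input checksums and all
    derived stage seeds).
    """
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = generate_experiment(config.experiment)
    input_paths = write_experiment(exp, outdir / "inputs")

    pc = PermutationConfig(
        n_reps=config.n_permutation_reps,
        seed=stage_seed(config.seed, "permutation"),
        context_matched=config.context_matched,
        collapse_strand=config.collapse_strand,
    )
    result = analyze_experiment(exp, config.filter, pc)

    write_fixation_records(result.records, outdir / "fixations.tsv")
    with open(outdir / "filter_report.tsv", "w") as fh:
        fh.write("rule\tremoved\n")
        for rule, n in result.filter_report.removal_counts.items():
            fh.write(f"{rule}\t{n}\n")
        fh.write(f"survivors\t{len(result.filter_report.survivors)}\n")
    for lin, nulls in result.effect_nulls.items():
        for name, r in nulls.items():
            with open(outdir / f"null_{name}_{lin}.tsv", "w") as fh:
                fh.write("value\treplicates\n")
                for value in sorted(r.null_histogram):
                    fh.write(f"{value}\t{r.null_histogram[value]}\n")
    summary_json = _result_json(result)
    (outdir / "summary.json").write_text(
        json.dumps(summary_json, indent=2, sort_keys=True) + "\n"
    )

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "global_seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("generate", "permutation")
        },
        "inputs": {
            name: _sha256(Path(p)) for name, p in sorted(input_paths.items())
        },
        "row_counts": {
            "raw_calls": len(exp.calls),
            "surviving_calls": len(result.filter_report.survivors),
            "fixation_records": len(result.records),
            "ortholog_pairs": len(exp.ortholog_pairs),
        },
        "config": {
            "filter": dataclasses.asdict(config.filter or FilterConfig()),
            "n_permutation_reps": config.n_permutation_reps,
            "context_matched": config.context_matched,
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "report.md").write_text(make_report_text(summary_json))
    return outdir


def make_report(run_dir: str | Path) -> str:
    """Render the human-readable report for an existing run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json under {run_dir}")
    summary = json.loads(summary_path.read_text())
    return make_report_text(summary)


def make_report_text(s: Mapping) -> str:
    lines = ["# Evolution-experiment analysis report", ""]
    lines += [
        "## Fixation summary",
        f"- total fixations: {s['n_fixations']} ({s['n_snvs']} SNVs)",
        f"- per-lineage SNVs: {s['per_lineage_snvs']}",
        f"- transition share (%): {s['transition_share_percent']}",
        f"- shares of all fixations (%): {s['shares_percent']}",
        f"- filter removals: {s['filter_removals']}",
        "",
        "## Permutation nulls",
    ]
    for lin, nulls in s.get("effect_nulls", {}).items():
        for name, r in nulls.items():
            lines.append(
                f"- lineage {lin} {name}: observed {r['observed']}, "
                f"p = {r['p']:.4g} ({r['n_reps']} reps)"
            )
    if "parallel_null" in s:
        pn = s["parallel_null"]
        lines.append(
            f"- parallel genes (>=2 protein-altering SNVs): observed "
            f"{pn['observed']}, p = {pn['p']:.4g}"
        )
    lines += ["", "## Conservation enrichment"]
    for key in ("background_ortholog_fraction", "nonsense_ortholog_p",
                "missense_ortholog_p", "background_conserved_fraction",
                "site_conservation_p", "miyata_mean_experimental",
                "miyata_mean_divergence", "miyata_t_p"):
        if key in s.get("conservation", {}):
            v = s["conservation"][key]
            lines.append(f"- {key}: {v:.4g}" if isinstance(v, float) else
                         f"- {key}: {v}")
    lines += ["", "## Evolutionary statistics"]
    if "dnds" in s:
        d = s["dnds"]
        ratio = "inf" if d["ratio"] is None else f"{d['ratio']:.3f}"
        lines.append(
            f"- dN/dS = {ratio} (N={d['observed_nonsyn']}, "
            f"S={d['observed_syn']}; binomial p = {d['binomial_p']:.3g})"
        )
    if "accumulation" in s:
        a = s["accumulation"]
        lines.append(
            f"- accumulation slope = {a['slope']:.3g} per passage^2 "
            f"(p = {a['slope_p']:.3g})"
        )
    if "passages_per_fixation" in s:
        p = s["passages_per_fixation"]
        lines.append(
            f"- passages per fixation: {p['raw']:.2f} (~{p['rounded']})"
        )
    if "mutator" in s:
        m = s["mutator"]
        lines.append(
            f"- mutator ANOVA: lineage p = {m['lineage_p']:.3g}, "
            f"population p = {m['population_p']:.3g}"
        )
    return "\n".join(lines) + "\n"
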