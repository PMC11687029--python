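"""End-to-end workflow: simulate an rDNA array, observe it through three
detection arms, call and filter variants, reconcile them across methods, and
summarize distances, haplotypes, and copy number.

A :class:`PipelineConfig` fully determines a run: two invocations with the
same config produce byte-identical report bundles.  Per-stage random seeds
are derived from the master seed through a :class:`numpy.random.SeedSequence`
so the stages are statistically independent but reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as rio
from .calling import (
    HardFilterThresholds,
    METHOD_AMPLICON,
    METHOD_CLONING,
    METHOD_WGS,
    Pileup,
    VariantTable,
    build_pileup,
    call_variants,
    detect_clone_variants,
)
from .copynumber import estimate_rdna_copy_number, mapping_stats_from_reads
from .distance import (
    count_haplotypes,
    distance_summary,
    neighbor_joining,
    p_distance_matrix,
)
from .errors import PipelineStageError
from .reconcile import (
    ConsensusRecord,
    classify_conflicts,
    compute_run_consistency,
    conflict_tally,
    correct_clone_alignment,
    merge_methods,
)
from .sequencing import sample_clones, simulate_amplicon_reads, simulate_wgs_reads
from .simulate import (
    HeterogeneityModel,
    RdnaUnit,
    assemble_genome,
    evolve_haplotypes,
    make_reference_unit,
)

REPORT_REGIONS = ("18S", "ITS", "28S")


@dataclass
class PipelineConfig:
    """Serializable description of one full simulated study."""

    seed: int = 1
    # reference unit
    region_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "18S": 300, "ITS1": 200, "5.8S": 160, "ITS2": 232, "28S": 300
        }
    )
    gc: float = 0.5
    # heterogeneity
    mode: str = "accumulated_mutation"
    n_haplotypes: int = 4
    region_rates: dict[str, float] = field(
        default_factory=lambda: {"ITS": 0.0065, "18S": 0.0005, "28S": 0.0005}
    )
    indel_rate: float = 0.0005
    indel_region: str | None = None
    hybrid_divergence: float | None = None
    insert_length: int | None = None
    total_copies: int = 20
    min_copy_frac: float = 0.1
    # cloning arm
    n_clones: int = 15
    clone_error_rate: float = 5e-4
    clone_region: str = "ITS"
    # amplicon arm
    amplicon_regions: list[str] = field(default_factory=lambda: ["ITS"])
    amplicon_depth: int = 2000
    amplicon_read_length: int = 150
    amplicon_error_rate: float = 1e-3
    n_runs: int = 2
    run_depth_jitter: float = 0.2
    # WGS arm
    background_len: int = 12000
    collapse_in_assembly: bool = False
    wgs_coverage: float = 10.0
    wgs_read_length: int = 150
    wgs_error_rate: float = 1e-3
    # calling & reconciliation
    base_error: float = 1e-3
    min_alt_count: int = 5
    thresholds: dict[str, float] = field(
        default_factory=lambda: dataclasses.asdict(HardFilterThresholds())
    )
    identity_floor: float = 0.9
    edge_window: int = 50
    gap_mode: str = "pairwise_deletion"

    def heterogeneity_model(self) -> HeterogeneityModel:
        return HeterogeneityModel(
            mode=self.mode,
            n_haplotypes=self.n_haplotypes,
            region_rates=dict(self.region_rates),
            indel_rate=self.indel_rate,
            indel_region=self.indel_region,
            hybrid_divergence=self.hybrid_divergence,
            insert_length=self.insert_length,
        )

    def hard_filters(self) -> HardFilterThresholds:
        return HardFilterThresholds(**self.thresholds)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    def save(self, path) -> None:
        rio.save_config(self.to_dict(), path)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(rio.load_config(path))


@dataclass
class PipelineResult:
    config: PipelineConfig
    unit: RdnaUnit
    hapset: object
    genome: object
    clone_table: VariantTable
    amplicon_tables: list[VariantTable]
    wgs_table: VariantTable
    records: list[ConsensusRecord]
    clone_alignment: object
    corrected_alignment: object
    correction_report: object
    region_summary: pd.DataFrame
    conflict_summary: dict[str, int]
    copy_number: float
    mapping_stats: object
    recovery: dict
    haplotype_count_raw: int
    haplotype_count_corrected: int
    trees: dict

    @property
    def consensus_keys(self) -> set[tuple[int, str]]:
        return {r.key for r in self.records if r.is_consensus}


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    """Execute the full workflow; optionally write the report bundle."""
    seeds = _stage_seeds(config.seed, 8)
    stage = "generate"
    try:
        unit = make_reference_unit(config.region_lengths, config.gc, seed=seeds[0])
        hapset = evolve_haplotypes(
            unit,
            config.heterogeneity_model(),
            seed=seeds[1],
            total_copies=config.total_copies,
            min_copy_frac=config.min_copy_frac,
        )
        genome = assemble_genome(
            hapset,
            background_len=config.background_len,
            collapse_in_assembly=config.collapse_in_assembly,
            seed=seeds[2],
        )

        stage = "simulate"
        clones = sample_clones(
            hapset,
            n_clones=config.n_clones,
            error_rate=config.clone_error_rate,
            seed=seeds[3],
            region=config.clone_region,
        )
        amplicon_runs: dict[str, list] = {}  # run_id -> list of ReadSet
        for ri, region in enumerate(config.amplicon_regions):
            runsets = simulate_amplicon_reads(
                hapset,
                region=region,
                depth=config.amplicon_depth,
                read_length=config.amplicon_read_length,
                error_rate=config.amplicon_error_rate,
                n_runs=config.n_runs,
                run_depth_jitter=config.run_depth_jitter,
                seed=seeds[4] + ri,
            )
            for rs in runsets:
                amplicon_runs.setdefault(rs.run_id, []).append(rs)
        wgs_reads = simulate_wgs_reads(
            genome,
            coverage=config.wgs_coverage,
            read_length=config.wgs_read_length,
            error_rate=config.wgs_error_rate,
            seed=seeds[5],
        )

        stage = "call"
        thresholds = config.hard_filters()
        clone_table, clone_alignment = detect_clone_variants(clones, unit)
        amplicon_tables: list[VariantTable] = []
        amplicon_pileups: dict[str, list[Pileup]] = {}
        for run_id, runsets in amplicon_runs.items():
            calls = []
            depths = []
            for rs in runsets:
                start, end = unit.span(rs.region)
                pileup = build_pileup(
                    rs,
                    unit.sequence[start - 1 : end],
                    offset=start,
                    identity_floor=config.identity_floor,
                )
                amplicon_pileups.setdefault(run_id, []).append(pileup)
                t = call_variants(
                    pileup,
                    base_error=config.base_error,
                    min_alt_count=config.min_alt_count,
                    thresholds=thresholds,
                    method=METHOD_AMPLICON,
                    run_id=run_id,
                )
                calls.extend(t.calls)
                depths.append(t.mean_depth)
            amplicon_tables.append(
                VariantTable(
                    calls=sorted(calls, key=lambda c: (c.position, c.alt_allele)),
                    mean_depth=float(np.mean(depths)),
                    method=METHOD_AMPLICON,
                    run_id=run_id,
                )
            )
        wgs_pileup = build_pileup(
            wgs_reads, unit, identity_floor=config.identity_floor
        )
        wgs_table = call_variants(
            wgs_pileup,
            base_error=config.base_error,
            min_alt_count=config.min_alt_count,
            thresholds=thresholds,
            method=METHOD_WGS,
            run_id="wgs",
        )

        stage = "reconcile"
        consistency = compute_run_consistency(amplicon_tables)
        records = merge_methods(
            cloning=clone_table, amplicon=consistency, wgs=wgs_table
        )
        amplicon_spans = [unit.span(r) for r in config.amplicon_regions]
        reference_check = _reference_check(
            records, amplicon_pileups, wgs_pileup
        )
        records = classify_conflicts(
            records,
            amplicon_spans=amplicon_spans,
            edge_window=config.edge_window,
            reference_check=reference_check,
        )
        corrected_alignment, correction_report = correct_clone_alignment(
            clone_alignment, records, gap_mode=config.gap_mode
        )

        stage = "phylo"
        n_raw, _ = count_haplotypes(clone_alignment)
        n_corr, _ = count_haplotypes(corrected_alignment)
        trees = {}
        if len(clone_alignment.clone_ids) >= 3:
            d_raw = p_distance_matrix(clone_alignment, gap_mode=config.gap_mode)
            d_corr = p_distance_matrix(
                corrected_alignment, gap_mode=config.gap_mode
            )
            trees["raw"] = neighbor_joining(d_raw)
            trees["corrected"] = neighbor_joining(d_corr)

        stage = "copy_number"
        mapping_stats = mapping_stats_from_reads(
            wgs_reads,
            unit,
            genome.assembly_sequence,
            identity_floor=config.identity_floor,
        )
        copy_number = estimate_rdna_copy_number(mapping_stats)

        stage = "report"
        region_summary = _region_summary(
            unit, records, clone_table, amplicon_tables, wgs_table,
            n_clones=len(clones.clones), n_runs=config.n_runs,
        )
        conflict_summary = conflict_tally(records)
        recovery = _recovery_metrics(hapset, records)

        result = PipelineResult(
            config=config,
            unit=unit,
            hapset=hapset,
            genome=genome,
            clone_table=clone_table,
            amplicon_tables=amplicon_tables,
            wgs_table=wgs_table,
            records=records,
            clone_alignment=clone_alignment,
            corrected_alignment=corrected_alignment,
            correction_report=correction_report,
            region_summary=region_summary,
            conflict_summary=conflict_summary,
            copy_number=copy_number,
            mapping_stats=mapping_stats,
            recovery=recovery,
            haplotype_count_raw=n_raw,
            haplotype_count_corrected=n_corr,
            trees=trees,
        )
        if outdir is not None:
            stage = "write"
            _write_bundle(result, outdir)
        return result
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc


def _reference_check(
    records: list[ConsensusRecord],
    amplicon_pileups: dict[str, list[Pileup]],
    wgs_pileup: Pileup,
) -> dict[int, dict[str, int]]:
    """Reference-base read support per covering read-based method."""
    out: dict[int, dict[str, int]] = {}
    for rec in records:
        pos = rec.position
        support: dict[str, int] = {}
        amp_total, amp_covered = 0, False
        for pileups in amplicon_pileups.values():
            for p in pileups:
                if p.offset <= pos < p.offset + p.length:
                    i = pos - p.offset
                    if p.depth()[i] > 0:
                        amp_covered = True
                        amp_total += p.ref_support(pos)
        if amp_covered:
            support[METHOD_AMPLICON] = amp_total
        if wgs_pileup.offset <= pos < wgs_pileup.offset + wgs_pileup.length:
            if wgs_pileup.depth()[pos - wgs_pileup.offset] > 0:
                support[METHOD_WGS] = wgs_pileup.ref_support(pos)
        if support:
            out[pos] = support
    return out


def _is_indel(alt: str) -> bool:
    return alt == "-" or alt.startswith("+")


def _region_summary(
    unit: RdnaUnit,
    records: list[ConsensusRecord],
    clone_table: VariantTable,
    amplicon_tables: list[VariantTable],
    wgs_table: VariantTable,
    n_clones: int,
    n_runs: int,
) -> pd.DataFrame:
    """Per-region 'substitutions/indels [n]' tallies per detection method.

    A site counts for a method when that method detected it and the site is
    not attributed to an artefact of that same method (singleton cloning
    artefacts are excluded from the cloning cell, false amplicon calls from
    the amplicon cell)."""
    from .reconcile import (
        VERDICT_AMPLICON_FALSE_CALL,
        VERDICT_CLONING_ARTIFACT,
        VERDICT_RUN_INCONSISTENT,
    )

    rows = []
    excluded_for = {
        METHOD_CLONING: {VERDICT_CLONING_ARTIFACT},
        METHOD_AMPLICON: {VERDICT_AMPLICON_FALSE_CALL, VERDICT_RUN_INCONSISTENT},
        METHOD_WGS: set(),
    }
    for region in REPORT_REGIONS:
        start, end = unit.span(region)
        row = {"region": region, "length": end - start + 1}
        for method, suffix in (
            (METHOD_AMPLICON, f"[{n_runs}]"),
            (METHOD_WGS, ""),
            (METHOD_CLONING, f"[{n_clones}]"),
        ):
            subs = indels = 0
            seen_positions: set[tuple[int, str]] = set()
            for rec in records:
                if not start <= rec.position <= end:
                    continue
                if method not in rec.methods_detected:
                    continue
                if rec.verdict in excluded_for[method]:
                    continue
                if rec.key in seen_positions:
                    continue
                seen_positions.add(rec.key)
                if _is_indel(rec.alt_allele):
                    indels += 1
                else:
                    subs += 1
            row[method] = f"{subs}/{indels} {suffix}".strip()
        rows.append(row)
    return pd.DataFrame(rows)


def _recovery_metrics(hapset, records: list[ConsensusRecord]) -> dict:
    truth = hapset.truth_keys()
    consensus = {r.key for r in records if r.is_consensus}
    tp = truth & consensus
    return {
        "n_true_sites": len(truth),
        "n_consensus": len(consensus),
        "n_recovered": len(tp),
        "sensitivity": len(tp) / len(truth) if truth else float("nan"),
        "false_consensus": sorted(consensus - truth),
        "n_false_consensus": len(consensus - truth),
        "missed": sorted(truth - consensus),
    }


def _write_bundle(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    cfg = result.config
    unit = result.unit
    rio.write_fasta([("rDNA_unit", unit.sequence)], os.path.join(outdir, "unit.fasta"))
    rio.write_fasta(result.hapset.haplotypes, os.path.join(outdir, "haplotypes.fasta"))
    rio.write_fasta(
        [("assembly", result.genome.assembly_sequence)],
        os.path.join(outdir, "assembly.fasta"),
    )
    truth_df = pd.DataFrame(
        [
            {"position": v.position, "ref": v.ref, "alt": v.alt, "frequency": v.frequency}
            for v in result.hapset.true_variant_sites
        ]
    )
    rio.write_tsv(truth_df, os.path.join(outdir, "truth.tsv"))

    rio.write_vcf(
        result.clone_table,
        os.path.join(outdir, "variants_cloning.vcf"),
        contig_length=unit.length,
        reference=unit.sequence,
    )
    for t in result.amplicon_tables:
        rio.write_vcf(
            t,
            os.path.join(outdir, f"variants_amplicon_{t.run_id}.vcf"),
            contig_length=unit.length,
            reference=unit.sequence,
        )
    rio.write_vcf(
        result.wgs_table,
        os.path.join(outdir, "variants_wgs.vcf"),
        contig_length=unit.length,
        reference=unit.sequence,
    )

    rec_rows = []
    for r in result.records:
        rec_rows.append(
            {
                "position": r.position,
                "ref": r.ref_base,
                "alt": r.alt_allele,
                "methods_detected": ",".join(sorted(r.methods_detected)),
                "clone_support": r.clone_support,
                "clone_frequency": r.clone_frequency,
                "amplicon_mean_frequency": (
                    r.amplicon.mean_frequency if r.amplicon else None
                ),
                "amplicon_runs_present": (
                    len(r.amplicon.present_runs) if r.amplicon else 0
                ),
                "wgs_frequency": r.wgs_frequency,
                "verdict": r.verdict,
                "conflict": r.conflict,
            }
        )
    rio.write_tsv(pd.DataFrame(rec_rows), os.path.join(outdir, "consensus.tsv"))
    rio.write_tsv(result.region_summary, os.path.join(outdir, "region_summary.tsv"))

    for name, tree in result.trees.items():
        rio.write_newick(tree, os.path.join(outdir, f"nj_{name}.nwk"))

    report = {
        "seed": cfg.seed,
        "copy_number_estimate": result.copy_number,
        "copy_number_true": result.genome.total_rdna_copies,
        "mapping": {
            "pct_reads_on_rdna": result.mapping_stats.pct_reads_on_rdna,
            "pct_reads_on_assembly": result.mapping_stats.pct_reads_on_assembly,
            "rdna_length": result.mapping_stats.rdna_length,
            "assembly_size": result.mapping_stats.assembly_size,
        },
        "haplotypes": {
            "true": len(result.hapset.haplotypes),
            "raw": result.haplotype_count_raw,
            "corrected": result.haplotype_count_corrected,
        },
        "p_distance": {
            "raw_max": result.correction_report.raw_max_p_distance,
            "raw_mean": result.correction_report.raw_mean_p_distance,
            "corrected_max": result.correction_report.corrected_max_p_distance,
            "corrected_mean": result.correction_report.corrected_mean_p_distance,
        },
        "variant_sites": {
            "raw": result.correction_report.raw_variant_sites,
            "corrected": result.correction_report.corrected_variant_sites,
            "masked_columns": result.correction_report.masked_columns,
        },
        "conflicts": result.conflict_summary,
        "recovery": result.recovery,
    }
    with open(os.path.join(outdir, "report.json"), "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    cfg.save(os.path.join(outdir, "config.yaml"))
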