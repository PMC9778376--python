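"""End-to-end screening pipeline: one config in, report tables out.

Order of operations is fixed: call-rate filtering, regional extraction and
MAF classification, predictive-marker assignment, LD profiling and
perfect-LD collapse, phenotype normalization and age-correction, staging,
genotype-stratified comparisons, cohort summaries. The analysis path is
fully deterministic; a run manifest records every parameter. An internal
consistency audit recomputes group counts and MAFs from the emitted
per-dog and per-marker tables and fails the run on any mismatch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import compare_by_genotype, stratify_by_genotype, summarize_cohort
from .echo import adjust_cohort
from .io import (
    read_phenotypes,
    read_plink_text,
    read_variant_table,
    read_vcf,
    write_tsv,
)
from .linkage import collapse_perfect_ld, genotype_r2
from .model import (
    AdjustedEcho,
    EchoRecord,
    GenotypeCohort,
    GroupComparison,
    HaplotypeGroup,
    RegionScan,
    RiskVariant,
    StagingConfig,
    ValidationError,
)
from .screen import (
    assign_predictive_markers,
    cohort_mafs,
    filter_call_rate,
    genotype_counts,
    minor_allele_frequency,
    round_half_away,
    scan_region,
)

log = logging.getLogger(__name__)

DEFAULT_WINDOW_HALF_WIDTH = 500_000


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters plus input/output locations."""

    genotype_format: str = "plink"  # "plink" | "vcf"
    map_path: str | None = None
    ped_path: str | None = None
    vcf_path: str | None = None
    phenotype_path: str | None = None
    variant_table_path: str | None = None
    region_windows: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    maf_threshold: float = 0.05
    call_rate_threshold: float = 0.90
    max_downstream_bp: int = 8000
    ld_tolerance: float = 1e-9
    ld_method: str = "composite"
    target_age: float = 8.0
    staging: StagingConfig = field(default_factory=StagingConfig)
    stage_on_adjusted: bool = False
    shared_age_fit: bool = False
    alpha: float = 0.05
    grouping: str = "het_only"
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValidationError("maf_threshold must be in [0, 0.5]")
        if not 0.0 <= self.call_rate_threshold <= 1.0:
            raise ValidationError("call_rate_threshold must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        staging = StagingConfig(**raw.pop("staging", {}))
        windows = {
            g: (str(w[0]), int(w[1]), int(w[2]))
            for g, w in raw.pop("region_windows", {}).items()
        }
        return cls(staging=staging, region_windows=windows, **raw)


@dataclass
class ScreenResult:
    """Everything the screen computed, for programmatic consumers."""

    cohort: GenotypeCohort
    dropped_markers: list[str]
    variants: list[RiskVariant]
    regions: dict[str, RegionScan]
    ld_pairs: list
    haplotype_groups: list[HaplotypeGroup]
    records: list[EchoRecord]
    adjusted: list[AdjustedEcho]
    comparisons: list[GroupComparison]
    summaries: dict[str, dict]
    frequency_table: pd.DataFrame
    n_tests: int


def _load_cohort(config: PipelineConfig) -> GenotypeCohort:
    if config.genotype_format == "plink":
        if not (config.map_path and config.ped_path):
            raise ValidationError("plink format requires map_path and ped_path")
        return read_plink_text(config.map_path, config.ped_path)
    if config.genotype_format == "vcf":
        if not config.vcf_path:
            raise ValidationError("vcf format requires vcf_path")
        return read_vcf(config.vcf_path)
    raise ValidationError(f"unknown genotype format {config.genotype_format!r}")


def _gene_window(
    gene: str, variants: list[RiskVariant], config: PipelineConfig
) -> tuple[str, int, int]:
    if gene in config.region_windows:
        return config.region_windows[gene]
    positions = [v.pos for v in variants]
    chroms = {v.chrom for v in variants}
    if len(chroms) != 1:
        raise ValidationError(f"gene {gene}: variants span chromosomes {sorted(chroms)}")
    return (
        chroms.pop(),
        max(1, min(positions) - DEFAULT_WINDOW_HALF_WIDTH),
        max(positions) + DEFAULT_WINDOW_HALF_WIDTH,
    )


def _frequency_table(cohort: GenotypeCohort, marker_ids: list[str]) -> pd.DataFrame:
    rows = []
    for mid in marker_ids:
        m = cohort.marker(mid)
        counts = genotype_counts(cohort, mid)
        maf, minor_is_ref = minor_allele_frequency(counts)
        a1, a2 = (m.allele_ref, m.allele_alt) if minor_is_ref else (m.allele_alt, m.allele_ref)
        rows.append(
            {
                "CHR": m.chrom,
                "SNP": mid,
                "A1": a1,
                "A2": a2,
                "MAF": round_half_away(maf, 2),
                "NCHROBS": 2 * counts.n_called,
            }
        )
    return pd.DataFrame(rows)


def run_screen(
    config: PipelineConfig,
    cohort: GenotypeCohort | None = None,
    records: list[EchoRecord] | None = None,
    variants: list[RiskVariant] | None = None,
    write_outputs: bool = True,
) -> ScreenResult:
    """Run the full screen; inputs may be preloaded or read from paths."""
    if cohort is None:
        cohort = _load_cohort(config)
    if records is None:
        if not config.phenotype_path:
            raise ValidationError("phenotype_path required")
        records = read_phenotypes(config.phenotype_path)
    if variants is None:
        if not config.variant_table_path:
            raise ValidationError("variant_table_path required")
        variants = read_variant_table(config.variant_table_path)

    # 1. call-rate filter precedes all frequency computation
    cohort, dropped = filter_call_rate(cohort, config.call_rate_threshold)

    # 2. regional MAF scans and fixation classification
    by_gene: dict[str, list[RiskVariant]] = {}
    for v in variants:
        by_gene.setdefault(v.gene, []).append(v)
    regions: dict[str, RegionScan] = {}
    for gene, vs in by_gene.items():
        chrom, start, end = _gene_window(gene, vs, config)
        regions[gene] = scan_region(cohort, gene, chrom, start, end, config.maf_threshold)

    # 3. predictive marker assignment
    variants = assign_predictive_markers(variants, cohort, config.max_downstream_bp)

    # 4. LD among predictive markers per gene + perfect-LD collapse
    positions = {m.marker_id: m.pos for m in cohort.markers}
    ld_pairs = []
    for gene, vs in by_gene.items():
        mids = sorted({v.predictive_marker_id for v in vs}, key=lambda m: positions[m])
        for i in range(len(mids)):
            for j in range(i + 1, len(mids)):
                try:
                    ld_pairs.append(
                        genotype_r2(
                            cohort.dosage_vector(mids[i]),
                            cohort.dosage_vector(mids[j]),
                            method=config.ld_method,
                            marker_a=mids[i],
                            marker_b=mids[j],
                        )
                    )
                except ValidationError as exc:
                    log.info("LD %s-%s skipped: %s", mids[i], mids[j], exc)
    haplotype_groups = collapse_perfect_ld(ld_pairs, config.ld_tolerance, positions)

    # 5. phenotype normalization, age-correction, staging
    adjusted, fit_la, fit_lv = adjust_cohort(
        records,
        target_age=config.target_age,
        staging=config.staging,
        stage_on_adjusted=config.stage_on_adjusted,
        shared_fit=config.shared_age_fit,
    )

    # 6. genotype-stratified comparisons per haplotype group / marker
    targets: list[str | HaplotypeGroup] = []
    grouped = {m for g in haplotype_groups if len(g.member_markers) > 1 for m in g.member_markers}
    targets.extend(g for g in haplotype_groups if len(g.member_markers) > 1)
    targets.extend(
        mid
        for mid in sorted({v.predictive_marker_id for v in variants}, key=lambda m: positions[m])
        if mid not in grouped
    )
    comparisons = []
    for target in targets:
        for phen in ("la_ao_age8", "lvidd_n_age8"):
            comparisons.append(
                compare_by_genotype(
                    cohort, adjusted, target, phen, grouping=config.grouping, alpha=config.alpha
                )
            )
    n_tests = sum(1 for c in comparisons if c.skipped_reason is None)

    # 7. cohort summaries for each multi-member haplotype group target
    phenotyped = {r.dog_id for r in records}
    summaries: dict[str, dict] = {}
    for target in targets:
        name = target.group_id if isinstance(target, HaplotypeGroup) else target
        strata = stratify_by_genotype(cohort, target)
        groups = {
            "total": sorted(phenotyped),
            f"{name}_hom_risk": [s for s in strata.hom_risk if s in phenotyped],
            f"{name}_het": [s for s in strata.het if s in phenotyped],
        }
        if strata.hom_ref:
            groups[f"{name}_hom_ref"] = [s for s in strata.hom_ref if s in phenotyped]
        summaries[name] = summarize_cohort(records, adjusted, groups)

    freq_table = _frequency_table(
        cohort, sorted({v.predictive_marker_id for v in variants}, key=lambda m: positions[m])
    )

    result = ScreenResult(
        cohort=cohort,
        dropped_markers=dropped,
        variants=variants,
        regions=regions,
        ld_pairs=ld_pairs,
        haplotype_groups=haplotype_groups,
        records=records,
        adjusted=adjusted,
        comparisons=comparisons,
        summaries=summaries,
        frequency_table=freq_table,
        n_tests=n_tests,
    )
    if write_outputs:
        write_report(result, config)
    audit(result)
    return result


def write_report(result: ScreenResult, config: PipelineConfig) -> None:
    """Emit the report TSVs and run manifest into ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_tsv(result.frequency_table, out / "frequency.tsv")

    write_tsv(
        pd.DataFrame(
            {
                "gene": r.gene,
                "chrom": r.chrom,
                "window_start": r.window_start,
                "window_end": r.window_end,
                "n_markers": len(r.marker_mafs),
                "mean_maf": round_half_away(r.mean_maf, 2),
                "sd_maf": round_half_away(r.sd_maf, 2),
                "status": r.status,
            }
            for r in result.regions.values()
        ),
        out / "regions.tsv",
    )

    pos = {m.marker_id: m for m in result.cohort.markers}
    write_tsv(
        pd.DataFrame(
            {
                "CHR_A": pos[p.marker_a].chrom,
                "BP_A": pos[p.marker_a].pos,
                "SNP_A": p.marker_a,
                "CHR_B": pos[p.marker_b].chrom,
                "BP_B": pos[p.marker_b].pos,
                "SNP_B": p.marker_b,
                "R2": p.r2,
            }
            for p in result.ld_pairs
        ),
        out / "ld.tsv",
    )

    write_tsv(
        pd.DataFrame(
            {
                "dog_id": a.dog_id,
                "la_ao": a.la_ao,
                "lvidd_n": a.lvidd_n,
                "la_ao_age8": a.la_ao_age8,
                "lvidd_n_age8": a.lvidd_n_age8,
                "stage": a.stage.value,
            }
            for a in result.adjusted
        ),
        out / "adjusted.tsv",
    )

    write_tsv(
        pd.DataFrame(
            {
                "target": c.marker_or_group,
                "phenotype": c.phenotype_name,
                "n_hom_risk": c.n_hom_risk,
                "n_comparison": c.n_carrier,
                "mean_hom": round_half_away(c.mean_hom, 2) if c.mean_hom == c.mean_hom else "",
                "sd_hom": round_half_away(c.sd_hom, 2) if c.sd_hom == c.sd_hom else "",
                "mean_comparison": round_half_away(c.mean_carrier, 2) if c.mean_carrier == c.mean_carrier else "",
                "sd_comparison": round_half_away(c.sd_carrier, 2) if c.sd_carrier == c.sd_carrier else "",
                "f_stat": round_half_away(c.f_stat, 2) if c.skipped_reason is None else "",
                "f_crit": round_half_away(c.f_crit, 2) if c.skipped_reason is None else "",
                "f_p": f"{c.f_p:.4g}" if c.skipped_reason is None else "",
                "t_stat": round_half_away(abs(c.t_stat), 2) if c.skipped_reason is None else "",
                "t_p": f"{c.t_p:.4g}" if c.skipped_reason is None else "",
                "skipped": c.skipped_reason or "",
            }
            for c in result.comparisons
        ),
        out / "comparisons.tsv",
    )

    summary_rows = []
    for target, groups in result.summaries.items():
        for label, s in groups.items():
            summary_rows.append(
                {
                    "target": target,
                    "group": label,
                    "n": s["n"],
                    "n_male": s["n_male"],
                    "n_female": s["n_female"],
                    **{f"stage_{k}": v for k, v in s["stage_counts"].items()},
                    "pct_b2_or_above": s["pct_b2_or_above"],
                    "mean_age": round_half_away(s["mean_age"], 2),
                    "sd_age": round_half_away(s["sd_age"], 2),
                    "mean_la_ao_age8": round_half_away(s["mean_la_ao_age8"], 2),
                    "sd_la_ao_age8": round_half_away(s["sd_la_ao_age8"], 2),
                    "mean_lvidd_n_age8": round_half_away(s["mean_lvidd_n_age8"], 2),
                    "sd_lvidd_n_age8": round_half_away(s["sd_lvidd_n_age8"], 2),
                }
            )
    write_tsv(pd.DataFrame(summary_rows), out / "summary.tsv")

    manifest = {
        "tool": "mmvdscreen",
        "version": __version__,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k != "out_dir"  # analysis parameters only, not run location
        },
        "n_samples": result.cohort.n_samples,
        "n_markers_post_filter": result.cohort.n_markers,
        "n_markers_dropped_call_rate": len(result.dropped_markers),
        "n_phenotyped": len(result.records),
        "n_statistical_tests": result.n_tests,
        "multiple_testing_correction": "none",
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def audit(result: ScreenResult) -> None:
    """Recompute report quantities from emitted per-dog/per-marker data.

    Group sizes, stage counts, percentages and rounded MAFs must agree
    exactly between the summary surfaces and a fresh recomputation from
    the underlying tables; any mismatch raises ``ValidationError``.
    """
    for target, groups in result.summaries.items():
        for label, s in groups.items():
            if sum(s["stage_counts"].values()) != s["n"]:
                raise ValidationError(f"audit: stage counts do not sum to n for {target}/{label}")
            if s["n"]:
                b2 = sum(c for k, c in s["stage_counts"].items() if k in ("B2", "C", "D"))
                if round_half_away(100.0 * b2 / s["n"], 0) != s["pct_b2_or_above"]:
                    raise ValidationError(f"audit: B2+ percentage mismatch for {target}/{label}")
    for _, row in result.frequency_table.iterrows():
        counts = genotype_counts(result.cohort, row["SNP"])
        maf, _ = minor_allele_frequency(counts)
        if round_half_away(maf, 2) != row["MAF"]:
            raise ValidationError(f"audit: MAF mismatch at {row['SNP']}")
        if 2 * counts.n_called != row["NCHROBS"]:
            raise ValidationError(f"audit: NCHROBS mismatch at {row['SNP']}")
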