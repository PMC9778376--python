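"""Fixation screening of candidate-gene regions on array genotypes.

A breed in which a derived risk allele has drifted to (near-)fixation shows
regionally depressed minor allele frequencies (MAFs) around the locus. The
screen computes per-marker MAFs and genotype counts, classifies each
candidate region as potentially fixed (mean MAF below a threshold, default
0.05) or polymorphic, and maps each off-array candidate variant to a
predictive array marker by proximity.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .model import (
    MISSING,
    GenotypeCohort,
    GenotypeCounts,
    MarkerDef,
    RegionScan,
    RiskVariant,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Regional mean MAF below this value flags potential allele fixation.
DEFAULT_MAF_THRESHOLD = 0.05

#: Maximum accepted distance (bp) to the nearest downstream array marker.
DEFAULT_MAX_DOWNSTREAM_BP = 8000


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (so 0.025 -> 0.03 at 2 digits).

    Numpy/Python banker's rounding would report 0.025 as 0.02; frequency
    tables here follow the spreadsheet convention instead.
    """
    if math.isnan(x):
        return x
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def genotype_counts(cohort: GenotypeCohort, marker_id: str) -> GenotypeCounts:
    """Tally genotype classes (hom-ref / het / hom-alt / missing) at a marker."""
    d = cohort.dosage_vector(marker_id)
    return GenotypeCounts(
        n_hom_ref=int(np.sum(d == 0)),
        n_het=int(np.sum(d == 1)),
        n_hom_alt=int(np.sum(d == 2)),
        n_missing=int(np.sum(d == MISSING)),
    )


def minor_allele_frequency(counts: GenotypeCounts) -> tuple[float, bool]:
    """Minor allele frequency and whether the minor allele is the reference.

    MAF = min(p_alt, 1 - p_alt) with p_alt = (n_het + 2 n_hom_alt) / (2 n_called).
    At exactly p_alt = 0.5 the alternate is reported as minor.
    """
    if counts.n_called == 0:
        raise ValidationError("MAF undefined: zero called genotypes")
    p_alt = (counts.n_het + 2 * counts.n_hom_alt) / (2 * counts.n_called)
    maf = min(p_alt, 1.0 - p_alt)
    minor_is_ref = p_alt > 0.5
    return maf, minor_is_ref


def cohort_mafs(cohort: GenotypeCohort) -> list[tuple[str, float]]:
    """Per-marker MAFs; markers with no calls are skipped with a log entry."""
    out = []
    for m in cohort.markers:
        counts = genotype_counts(cohort, m.marker_id)
        if counts.n_called == 0:
            log.warning("marker %s has no called genotypes; skipped", m.marker_id)
            continue
        out.append((m.marker_id, minor_allele_frequency(counts)[0]))
    return out


def filter_call_rate(
    cohort: GenotypeCohort, min_call_rate: float = 0.90
) -> tuple[GenotypeCohort, list[str]]:
    """Drop markers whose genotype call rate falls below ``min_call_rate``."""
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValidationError(f"min_call_rate must be in [0,1], got {min_call_rate}")
    called = np.sum(cohort.dosage != MISSING, axis=0) / cohort.n_samples
    keep = [j for j in range(cohort.n_markers) if called[j] >= min_call_rate]
    dropped = [cohort.markers[j].marker_id for j in range(cohort.n_markers) if called[j] < min_call_rate]
    if dropped:
        log.info("call-rate filter dropped %d markers: %s", len(dropped), dropped)
    if not keep:
        log.warning("call-rate filter removed every marker")
    return cohort.subset_markers(keep), dropped


def extract_region(cohort: GenotypeCohort, chrom: str, start: int, end: int) -> GenotypeCohort:
    """Markers with ``start <= pos <= end`` on ``chrom`` (closed interval)."""
    if start > end:
        raise ValidationError(f"region start {start} > end {end}")
    keep = [
        j
        for j, m in enumerate(cohort.markers)
        if m.chrom == chrom and start <= m.pos <= end
    ]
    return cohort.subset_markers(keep)


def classify_region(
    scan_mafs: list[float], threshold: float = DEFAULT_MAF_THRESHOLD
) -> tuple[float, float, str]:
    """Mean and sample SD of regional MAFs plus the fixation status.

    Status is ``potential_fixation`` iff mean MAF < threshold (strict, so a
    region averaging exactly at the threshold stays polymorphic).
    """
    if not scan_mafs:
        raise ValidationError("cannot classify an empty MAF list")
    arr = np.asarray(scan_mafs, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    status = "potential_fixation" if mean < threshold else "polymorphic"
    return mean, sd, status


def scan_region(
    cohort: GenotypeCohort,
    gene: str,
    chrom: str,
    start: int,
    end: int,
    threshold: float = DEFAULT_MAF_THRESHOLD,
) -> RegionScan:
    """Extract a region, compute its MAF profile and classify it."""
    sub = extract_region(cohort, chrom, start, end)
    mafs = cohort_mafs(sub)
    mean, sd, status = classify_region([m for _, m in mafs], threshold)
    return RegionScan(
        gene=gene,
        chrom=chrom,
        window_start=start,
        window_end=end,
        marker_mafs=mafs,
        mean_maf=mean,
        sd_maf=sd,
        status=status,
    )


def select_predictive_marker(
    variant: RiskVariant,
    markers: list[MarkerDef],
    max_downstream_bp: int = DEFAULT_MAX_DOWNSTREAM_BP,
) -> MarkerDef:
    """Choose the array marker that proxies an off-array candidate variant.

    Preference order: a marker at the variant's exact position; otherwise
    the nearest marker downstream (higher reference coordinate, the 3'
    direction on the forward strand) if it lies within ``max_downstream_bp``;
    otherwise the nearest upstream marker.
    """
    on_chrom = [m for m in markers if m.chrom == variant.chrom]
    if not on_chrom:
        raise ValidationError(f"no array marker on chromosome {variant.chrom} for {variant.name}")
    exact = [m for m in on_chrom if m.pos == variant.pos]
    if exact:
        return exact[0]
    downstream = [m for m in on_chrom if m.pos > variant.pos]
    if downstream:
        nearest_down = min(downstream, key=lambda m: m.pos - variant.pos)
        if nearest_down.pos - variant.pos <= max_downstream_bp:
            return nearest_down
    upstream = [m for m in on_chrom if m.pos < variant.pos]
    if not upstream:
        if downstream:
            return min(downstream, key=lambda m: m.pos - variant.pos)
        raise ValidationError(f"no marker flanking {variant.name}")
    return min(upstream, key=lambda m: variant.pos - m.pos)


def assign_predictive_markers(
    variants: list[RiskVariant],
    cohort: GenotypeCohort,
    max_downstream_bp: int = DEFAULT_MAX_DOWNSTREAM_BP,
) -> list[RiskVariant]:
    """Fill ``predictive_marker_id`` for every candidate variant.

    A variant whose table row carries an explicit representative array
    position uses the marker at that position directly (the candidate table
    is authoritative when it specifies one); the distance rule applies
    elsewhere.
    """
    by_pos = {(m.chrom, m.pos): m for m in cohort.markers}
    out = []
    for v in variants:
        if v.predictive_pos is not None:
            m = by_pos.get((v.chrom, v.predictive_pos))
            if m is None:
                raise ValidationError(
                    f"{v.name}: declared array location {v.chrom}:{v.predictive_pos} not in panel"
                )
        else:
            m = select_predictive_marker(v, cohort.markers, max_downstream_bp)
        v.predictive_marker_id = m.marker_id
        out.append(v)
    return out
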