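"""Readers and writers for genotype panels, phenotype tables and results.

Supported genotype formats are PLINK text (.ped/.map, whitespace-delimited,
"0" meaning a missing allele) and VCF v4.2 (GT subfield only, biallelic
records). Array files are assumed forward-strand: an allele that matches
neither declared allele at a marker is a validation error, never silently
complemented. Phenotype tables are CSV with a documented header; all result
writers emit TSV with a header line.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    EchoRecord,
    GenotypeCohort,
    MarkerDef,
    RiskVariant,
    ValidationError,
)

log = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}

#: Required phenotype CSV columns, in documented order.
PHENOTYPE_COLUMNS = [
    "dog_id",
    "sex",
    "age",
    "weight",
    "lvidd",
    "la",
    "ao",
    "murmur",
    "chf",
    "refractory",
]


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in ("1", "true", "t", "yes", "y"):
        return True
    if v in ("0", "false", "f", "no", "n"):
        return False
    raise ValidationError(f"cannot parse boolean field {value!r}")


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def read_plink_text(
    map_path: str | Path,
    ped_path: str | Path,
    alt_alleles: Mapping[str, tuple[str, str]] | None = None,
) -> GenotypeCohort:
    """Read a PLINK text fileset into a :class:`GenotypeCohort`.

    Dosages count the alternate allele. For markers listed in
    ``alt_alleles`` (marker_id -> (ref, alt), typically candidate sites
    from the risk-variant table) the declared alt is counted; elsewhere the
    alternate is the lexicographically later of the two observed alleles,
    a deterministic convention for files that carry no allele declaration.
    "0 0" genotype fields become missing. An observed allele that is
    neither declared ref nor alt raises :class:`ValidationError` naming the
    marker and sample.
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    marker_rows: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValidationError(f"{map_path}:{lineno}: expected 4 .map columns, got {len(parts)}")
        chrom, snp_id, _cm, pos = parts[0], parts[1], parts[2], parts[3]
        marker_rows.append((snp_id, chrom, int(pos)))

    n_markers = len(marker_rows)
    sample_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_markers:
            raise ValidationError(
                f"{ped_path}:{lineno}: ragged .ped line, expected {6 + 2 * n_markers} "
                f"fields for {n_markers} markers, got {len(parts)}"
            )
        sample_ids.append(parts[1])
        geno = parts[6:]
        allele_rows.append([(geno[2 * j], geno[2 * j + 1]) for j in range(n_markers)])

    alt_alleles = dict(alt_alleles or {})
    markers: list[MarkerDef] = []
    dosage = np.full((len(sample_ids), n_markers), MISSING, dtype=np.int8)
    for j, (snp_id, chrom, pos) in enumerate(marker_rows):
        observed = {a for row in allele_rows for a in row[j] if a != "0"}
        bad = observed - _BASES
        if bad:
            raise ValidationError(f"marker {snp_id}: non-IUPAC allele(s) {sorted(bad)}")
        if snp_id in alt_alleles:
            ref, alt = alt_alleles[snp_id]
            undeclared = observed - {ref, alt}
            if undeclared:
                sample = next(
                    s for s, row in zip(sample_ids, allele_rows) if undeclared & set(row[j])
                )
                raise ValidationError(
                    f"marker {snp_id}, sample {sample}: allele(s) {sorted(undeclared)} "
                    f"match neither declared ref {ref} nor alt {alt}"
                )
        elif len(observed) == 2:
            ref, alt = sorted(observed)  # alt = lexicographically later
        elif len(observed) == 1:
            ref, alt = observed.pop(), "N"
        else:  # entirely missing
            ref, alt = "N", "."
        markers.append(MarkerDef(snp_id, chrom, pos, ref, alt))
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == alt) + (a2 == alt)

    return GenotypeCohort(sample_ids=sample_ids, markers=markers, dosage=dosage)


def write_plink_text(cohort: GenotypeCohort, map_path: str | Path, ped_path: str | Path) -> None:
    """Write a cohort as a PLINK text fileset (inverse of the reader)."""
    with open(map_path, "w") as fh:
        for m in cohort.markers:
            fh.write(f"{m.chrom}\t{m.marker_id}\t0\t{m.pos}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(cohort.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, m in enumerate(cohort.markers):
                d = cohort.dosage[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [m.allele_ref, m.allele_ref]
                elif d == 1:
                    fields += [m.allele_ref, m.allele_alt]
                else:
                    fields += [m.allele_alt, m.allele_alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path: str | Path) -> GenotypeCohort:
    """Read a VCF into a :class:`GenotypeCohort` (GT subfield only).

    Only biallelic records are accepted; a multi-allelic ALT raises
    :class:`ValidationError` naming the position (split such records
    upstream, e.g. with ``bcftools norm``). Phase separators are ignored
    and ``./.`` becomes missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    markers: list[MarkerDef] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} (ALT={rec.ALT}); split before loading"
            )
        marker_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        markers.append(MarkerDef(marker_id, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        col = np.full(len(sample_ids), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        columns.append(col)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeCohort(sample_ids=sample_ids, markers=markers, dosage=dosage)


def write_vcf(cohort: GenotypeCohort, vcf_path: str | Path) -> None:
    """Write a cohort as a minimal VCF v4.2 with GT-only genotype fields."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(m.chrom for m in cohort.markers):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        for j, m in enumerate(cohort.markers):
            gts = "\t".join(gt_map[int(d)] for d in cohort.dosage[:, j])
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.marker_id}\t{m.allele_ref}\t{m.allele_alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes and candidate-variant tables
# ---------------------------------------------------------------------------

def read_phenotypes(csv_path: str | Path) -> list[EchoRecord]:
    """Read the per-dog phenotype CSV into typed :class:`EchoRecord` rows.

    Rows with any missing mandatory field are dropped with a logged count;
    a row that violates a value invariant (e.g. non-positive weight) raises
    :class:`ValidationError` with its row number.
    """
    csv_path = Path(csv_path)
    records: list[EchoRecord] = []
    n_dropped = 0
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(PHENOTYPE_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise ValidationError(f"{csv_path}: missing required columns {sorted(missing_cols)}")
        for rownum, row in enumerate(reader, start=2):
            if any(row.get(c) in (None, "", "NA") for c in PHENOTYPE_COLUMNS):
                n_dropped += 1
                continue
            try:
                records.append(
                    EchoRecord(
                        dog_id=row["dog_id"].strip(),
                        sex=row["sex"].strip().upper(),
                        age=float(row["age"]),
                        weight=float(row["weight"]),
                        lvidd=float(row["lvidd"]),
                        la=float(row["la"]),
                        ao=float(row["ao"]),
                        murmur=_parse_bool(row["murmur"]),
                        chf=_parse_bool(row["chf"]),
                        refractory=_parse_bool(row["refractory"]),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{csv_path}: row {rownum}: {exc}") from exc
    if n_dropped:
        log.warning("%s: dropped %d rows with missing mandatory fields", csv_path, n_dropped)
    if not records:
        log.warning("%s: no usable phenotype rows", csv_path)
    return records


def write_phenotypes(records: Iterable[EchoRecord], csv_path: str | Path) -> None:
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PHENOTYPE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.dog_id,
                    r.sex,
                    f"{r.age:.2f}",
                    f"{r.weight:.2f}",
                    f"{r.lvidd:.3f}",
                    f"{r.la:.3f}",
                    f"{r.ao:.3f}",
                    int(r.murmur),
                    int(r.chf),
                    int(r.refractory),
                ]
            )


def read_variant_table(tsv_path: str | Path) -> list[RiskVariant]:
    """Read the candidate risk-variant TSV.

    Columns: gene, variant, chrom, pos, allele_ref, allele_alt, and
    optionally array_chrom/array_pos giving the representative genotyping
    array location. When the array columns are present they preselect the
    predictive marker; otherwise nearest-downstream selection fills it in.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    variants = []
    for _, row in df.iterrows():
        pred_pos = None
        if "array_pos" in df.columns and not pd.isna(row.get("array_pos")):
            pred_pos = int(row["array_pos"])
        variants.append(
            RiskVariant(
                gene=str(row["gene"]),
                name=str(row["variant"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                allele_ref=str(row["allele_ref"]),
                allele_alt=str(row["allele_alt"]),
                predictive_pos=pred_pos,
            )
        )
    names = [v.name for v in variants]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate variant names in candidate table")
    return variants


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a header line."""
    df.to_csv(path, sep="\t", index=False)
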