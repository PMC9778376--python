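"""Core data model shared across the screening pipeline.

Genotypes are stored as alternate-allele dosages (0, 1, 2) in a compact
``int8`` matrix with ``MISSING`` (-1) as the sentinel for no-calls; a dosage
of 0 always means homozygous for the declared reference allele, never
"missing". Coordinates are 1-based inclusive (PLINK/VCF convention,
canFam3.1 assembly for the canine application) and all region arithmetic
uses closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

_VALID_DOSAGES = frozenset({0, 1, 2, MISSING})


class ValidationError(ValueError):
    """Input violated a documented invariant (bad allele, ragged row, ...)."""


class Stage(str, Enum):
    """ACVIM consensus severity stages for myxomatous mitral valve disease.

    A: at risk, no murmur. B1: murmur without cardiac enlargement.
    B2: murmur with enlargement. C: congestive heart failure (CHF).
    D: CHF refractory to treatment.
    """

    A = "A"
    B1 = "B1"
    B2 = "B2"
    C = "C"
    D = "D"


#: Stage ordering used for "B2 or above" style comparisons.
STAGE_ORDER = {Stage.A: 0, Stage.B1: 1, Stage.B2: 2, Stage.C: 3, Stage.D: 4}


@dataclass(frozen=True)
class MarkerDef:
    """A biallelic array marker: identifier, position and allele labels."""

    marker_id: str
    chrom: str
    pos: int
    allele_ref: str
    allele_alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"marker {self.marker_id}: pos must be >= 1, got {self.pos}")
        if self.allele_ref == self.allele_alt:
            raise ValidationError(
                f"marker {self.marker_id}: ref and alt alleles are both {self.allele_ref!r}"
            )


@dataclass
class GenotypeCohort:
    """Samples x markers matrix of alternate-allele dosages.

    ``dosage[i, j]`` counts copies of ``markers[j].allele_alt`` carried by
    ``sample_ids[i]``; ``MISSING`` marks a failed call. Markers are kept
    sorted by (chrom, pos) and strictly increasing within a chromosome.
    """

    sample_ids: list[str]
    markers: list[MarkerDef]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.markers)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.sample_ids)} samples, {len(self.markers)} markers)"
            )
        bad = set(np.unique(self.dosage)) - _VALID_DOSAGES
        if bad:
            raise ValidationError(f"invalid dosage values {sorted(bad)}")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate marker ids in panel")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in cohort")
        order = sorted(range(len(self.markers)), key=lambda j: (self.markers[j].chrom, self.markers[j].pos))
        if order != list(range(len(self.markers))):
            self.markers = [self.markers[j] for j in order]
            self.dosage = self.dosage[:, order]
        for a, b in zip(self.markers, self.markers[1:]):
            if a.chrom == b.chrom and a.pos >= b.pos:
                raise ValidationError(
                    f"markers {a.marker_id} and {b.marker_id} share chrom {a.chrom} pos {a.pos}"
                )
        self._index = {m.marker_id: j for j, m in enumerate(self.markers)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in panel") from None

    def marker(self, marker_id: str) -> MarkerDef:
        return self.markers[self.marker_index(marker_id)]

    def dosage_vector(self, marker_id: str) -> np.ndarray:
        """Dosage column for one marker (length ``n_samples``)."""
        return self.dosage[:, self.marker_index(marker_id)]

    def subset_markers(self, keep: Sequence[int]) -> "GenotypeCohort":
        keep = list(keep)
        return GenotypeCohort(
            sample_ids=list(self.sample_ids),
            markers=[self.markers[j] for j in keep],
            dosage=self.dosage[:, keep].copy(),
        )


@dataclass(frozen=True)
class EchoRecord:
    """One dog's clinical and echocardiographic record.

    Sizes are raw measurements: left-ventricular internal diameter in
    diastole (``lvidd``, cm), left atrial (``la``) and aortic root (``ao``)
    diameters in the same units as each other. Flags capture auscultated
    murmur, congestive heart failure, and failure refractory to treatment.
    """

    dog_id: str
    sex: str  # "M" or "F"
    age: float  # years
    weight: float  # kg
    lvidd: float  # cm
    la: float
    ao: float
    murmur: bool
    chf: bool
    refractory: bool

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"dog {self.dog_id}: sex must be M or F, got {self.sex!r}")
        if self.age < 0:
            raise ValidationError(f"dog {self.dog_id}: negative age {self.age}")
        for name in ("weight", "lvidd", "la", "ao"):
            v = getattr(self, name)
            if not v > 0:
                raise ValidationError(f"dog {self.dog_id}: {name} must be > 0, got {v}")
        if self.refractory and not self.chf:
            raise ValidationError(f"dog {self.dog_id}: refractory flag requires chf flag")


@dataclass
class RiskVariant:
    """A candidate risk locus and (optionally) its predictive array marker.

    The predictive marker is the on-array proxy genotyped in place of the
    off-array candidate variant; ``predictive_marker_id`` may be preset from
    a candidate table or filled by nearest-downstream selection.
    """

    gene: str
    name: str
    chrom: str
    pos: int
    allele_ref: str
    allele_alt: str
    predictive_marker_id: str | None = None
    predictive_pos: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.name}: pos must be >= 1")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class tally at one marker; classes partition the cohort."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt, self.n_missing) < 0:
            raise ValidationError("negative genotype count")

    @property
    def n_called(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def total(self) -> int:
        return self.n_called + self.n_missing


@dataclass
class RegionScan:
    """Per-region minor-allele-frequency summary and fixation call."""

    gene: str
    chrom: str
    window_start: int
    window_end: int
    marker_mafs: list[tuple[str, float]]
    mean_maf: float
    sd_maf: float
    status: str  # "potential_fixation" | "polymorphic"


@dataclass(frozen=True)
class LDPair:
    """Pairwise linkage disequilibrium (r^2) between two markers."""

    marker_a: str
    marker_b: str
    r2: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValidationError(f"r2 out of [0,1]: {self.r2}")


@dataclass
class HaplotypeGroup:
    """Markers in mutual (near-)perfect LD treated as one inherited unit."""

    group_id: str
    member_markers: set[str]
    representative: str

    def __post_init__(self) -> None:
        if self.representative not in self.member_markers:
            raise ValidationError("representative must be a group member")


@dataclass(frozen=True)
class RegressionFit:
    """Linear age model for an echo metric, anchored at a reference age.

    ``expected_at_target`` is the model's prediction at ``target_age``
    (default 8 years), the constant every observation is re-centred on.
    """

    slope: float
    intercept: float
    target_age: float = 8.0
    expected_at_target: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = self.slope * self.target_age + self.intercept
        if self.expected_at_target is None:
            object.__setattr__(self, "expected_at_target", expected)
        elif abs(self.expected_at_target - expected) > 1e-12:
            raise ValidationError("expected_at_target inconsistent with slope/intercept")

    def predict(self, age: float) -> float:
        return self.slope * age + self.intercept


@dataclass(frozen=True)
class StagingConfig:
    """Enlargement cutoffs used to separate ACVIM stage B1 from B2.

    Defaults follow the consensus guideline values: left-atrium-to-aorta
    ratio >= 1.6 and weight-normalised LVIDd >= 1.7, both required.
    """

    la_ao_b2_cutoff: float = 1.6
    lvidd_n_b2_cutoff: float = 1.7
    require_both: bool = True

    def __post_init__(self) -> None:
        if self.la_ao_b2_cutoff <= 0 or self.lvidd_n_b2_cutoff <= 0:
            raise ValidationError("staging cutoffs must be > 0")

    def enlarged(self, la_ao: float, lvidd_n: float) -> bool:
        a = la_ao >= self.la_ao_b2_cutoff
        b = lvidd_n >= self.lvidd_n_b2_cutoff
        return (a and b) if self.require_both else (a or b)


@dataclass
class AdjustedEcho:
    """Raw and age-8-corrected severity metrics plus the assigned stage."""

    dog_id: str
    la_ao: float
    lvidd_n: float
    la_ao_age8: float
    lvidd_n_age8: float
    stage: Stage


@dataclass
class GroupComparison:
    """Genotype-stratified variance (F) and means (Welch t) test results.

    The F statistic is oriented with the risk-homozygote group variance in
    the numerator (df1 = n_hom - 1, df2 = n_comparison - 1), matching the
    critical-value column convention of the source analysis.
    """

    marker_or_group: str
    phenotype_name: str
    n_hom_risk: int
    n_carrier: int
    mean_hom: float
    sd_hom: float
    mean_carrier: float
    sd_carrier: float
    f_stat: float
    df1: int
    df2: int
    f_crit: float
    f_p: float
    t_stat: float
    t_df: float
    t_p: float
    skipped_reason: str | None = None


__all__ = [
    "MISSING",
    "ValidationError",
    "Stage",
    "STAGE_ORDER",
    "MarkerDef",
    "GenotypeCohort",
    "EchoRecord",
    "RiskVariant",
    "GenotypeCounts",
    "RegionScan",
    "LDPair",
    "HaplotypeGroup",
    "RegressionFit",
    "StagingConfig",
    "AdjustedEcho",
    "GroupComparison",
    "replace",
]
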