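"""Synthetic cohort generation for end-to-end pipeline testing.

Two entry points:

* :func:`simulate_genotypes` / :func:`simulate_phenotypes` draw a cohort
  from a configurable generative model — Hardy-Weinberg genotypes with
  optional perfect-LD blocks, and echo metrics that rise linearly with age
  with a genotype-dependent mean and variance — so statistical behaviour
  (type-I error, parameter recovery) can be probed at any size.
* :func:`make_printed_fixture` builds one deterministic cohort whose
  marginal composition mirrors the published CKCS study cohort: 180
  genotyped dogs (178 phenotyped), a three-marker perfect-LD wild-type
  haplotype carried by 6 dogs, 17 carriers at the two mid-gene nebulette
  markers, 3 at the distal one, 7 heterozygous plus 1 homozygous-reference
  dog at the HDGFL1 marker, and the published ACVIM stage composition.

Per-dog metric values in the fixture are drawn from truncated normals
consistent with the published group means/SDs and stage cutoffs; only
summary statistics, never individual values, are meaningful test surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    MISSING,
    EchoRecord,
    GenotypeCohort,
    MarkerDef,
    RiskVariant,
    StagingConfig,
    ValidationError,
)

#: Candidate risk variants with their representative array locations, as
#: published for the canine MMVD candidate loci (canFam3.1, 1-based).
PRINTED_VARIANTS: list[tuple[str, str, str, int, str, str, int]] = [
    # gene, variant, chrom, variant pos, ref, alt, array marker pos
    ("NEBL", "NEBL1", "2", 11_816_535, "A", "G", 11_822_980),
    ("NEBL", "NEBL2", "2", 11_823_576, "C", "T", 11_832_538),
    ("NEBL", "NEBL3", "2", 11_979_724, "G", "A", 11_979_724),
    ("NEBL", "NEBL4", "2", 12_082_890, "T", "C", 12_085_928),
    ("NEBL", "NEBL5", "2", 12_165_498, "A", "T", 12_174_951),
    ("NEBL", "NEBL6", "2", 12_567_546, "A", "G", 12_567_760),
    ("LPHN2", "LPHN2", "6", 65_609_405, "T", "C", 65_607_149),
    ("HDGFL1", "HDGFL1", "7", 41_245_057, "A", "G", 41_248_384),
    ("SORBS2", "SORBS2", "16", 45_026_823, "C", "T", 45_035_960),
    ("HTR1F", "HTR1F", "31", 273_549, "T", "C", 273_549),
]

#: Region windows used for the regional MAF scans (1-based, closed).
REGION_WINDOWS: dict[str, tuple[str, int, int]] = {
    "NEBL": ("2", 11_650_000, 12_650_000),
    "LPHN2": ("6", 65_109_000, 66_110_000),
    "HDGFL1": ("7", 40_745_000, 41_746_000),
    "SORBS2": ("16", 44_526_000, 45_527_000),
    "HTR1F": ("31", 1, 773_000),
}


def printed_variant_table() -> list[RiskVariant]:
    """The candidate-variant table as :class:`RiskVariant` rows."""
    return [
        RiskVariant(
            gene=g, name=n, chrom=c, pos=p, allele_ref=r, allele_alt=a, predictive_pos=ap
        )
        for g, n, c, p, r, a, ap in PRINTED_VARIANTS
    ]


@dataclass
class BlockSpec:
    """A set of markers sharing a wild-type-allele frequency.

    ``block_maf`` is the frequency of the reference (wild-type) allele —
    the minor allele near fixation of the risk allele. With ``perfect_ld``
    every dog's genotype is identical across member markers.
    """

    chrom: str
    positions: list[int]
    block_maf: float
    perfect_ld: bool = True
    label: str = "block"


@dataclass
class MetricModel:
    """Generative model for one echo metric.

    metric = intercept + age_slope * age + carrier_effect * 1[carrier]
             + Normal(0, sd_hom or sd_carrier)
    """

    intercept: float
    age_slope: float
    carrier_effect: float
    sd_hom: float
    sd_carrier: float


def _default_blocks() -> list[BlockSpec]:
    return [
        BlockSpec(
            chrom="2",
            positions=[11_822_980, 11_832_538, 11_979_724],
            block_maf=0.017,
            perfect_ld=True,
            label="nebl_proximal",
        )
    ]


@dataclass
class SimulationConfig:
    """Study-scale defaults: a 180-dog cohort with one near-fixed
    three-marker wild-type haplotype and published group-level effect
    sizes (carrier effects -0.37 on LA:Ao and -0.26 on LVIDdN, group SDs
    0.63/0.21 and 0.46/0.16, age slope 0.038 per year)."""

    n_dogs: int = 180
    blocks: list[BlockSpec] = field(default_factory=_default_blocks)
    fill_markers: int = 40
    fill_maf_range: tuple[float, float] = (0.05, 0.5)
    fill_chrom: str = "10"
    fill_start: int = 1_000_000
    fill_step: int = 5_000
    missing_rate: float = 0.01
    age_dist: tuple[float, float] = (10.0, 1.96)  # years
    weight_dist: tuple[float, float] = (8.4, 1.4)  # kg
    ao_dist: tuple[float, float] = (1.45, 0.12)  # aortic root, cm
    la_ao_model: MetricModel = field(
        default_factory=lambda: MetricModel(1.436, 0.038, -0.37, 0.63, 0.21)
    )
    lvidd_n_model: MetricModel = field(
        default_factory=lambda: MetricModel(1.576, 0.038, -0.26, 0.46, 0.16)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dogs < 2:
            raise ValidationError("n_dogs must be >= 2")
        for b in self.blocks:
            if not 0.0 <= b.block_maf <= 0.5:
                raise ValidationError(f"block {b.label}: MAF must be in [0, 0.5]")
            if len(set(b.positions)) != len(b.positions):
                raise ValidationError(f"block {b.label}: duplicate positions")
        for m in (self.la_ao_model, self.lvidd_n_model):
            if m.sd_hom <= 0 or m.sd_carrier <= 0:
                raise ValidationError("metric model SDs must be > 0")


def _hwe_wildtype_copies(rng: np.random.Generator, n: int, wt_freq: float) -> np.ndarray:
    """Per-dog wild-type allele count at Hardy-Weinberg proportions."""
    return rng.binomial(2, wt_freq, size=n)


def simulate_genotypes(config: SimulationConfig) -> GenotypeCohort:
    """Draw a genotype panel from the block + background model.

    The risk (alternate) allele is the major allele at block markers, so
    alternate dosage = 2 - (wild-type copies). Background markers are
    independent draws at Hardy-Weinberg proportions from MAFs uniform in
    ``fill_maf_range``. Missingness is applied uniformly at random; the
    whole panel is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"D{i + 1:03d}" for i in range(config.n_dogs)]
    markers: list[MarkerDef] = []
    cols: list[np.ndarray] = []

    seen: set[tuple[str, int]] = set()
    for block in config.blocks:
        shared = _hwe_wildtype_copies(rng, config.n_dogs, block.block_maf)
        for pos in block.positions:
            if (block.chrom, pos) in seen:
                raise ValidationError(f"duplicate marker position {block.chrom}:{pos}")
            seen.add((block.chrom, pos))
            wt = shared if block.perfect_ld else _hwe_wildtype_copies(
                rng, config.n_dogs, block.block_maf
            )
            markers.append(MarkerDef(f"arr{block.chrom}_{pos}", block.chrom, pos, "A", "G"))
            cols.append((2 - wt).astype(np.int8))

    for k in range(config.fill_markers):
        pos = config.fill_start + k * config.fill_step
        maf = rng.uniform(*config.fill_maf_range)
        wt = _hwe_wildtype_copies(rng, config.n_dogs, maf)
        markers.append(MarkerDef(f"arr{config.fill_chrom}_{pos}", config.fill_chrom, pos, "A", "G"))
        cols.append((2 - wt).astype(np.int8))

    dosage = np.column_stack(cols) if cols else np.empty((config.n_dogs, 0), dtype=np.int8)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = MISSING
    return GenotypeCohort(sample_ids=sample_ids, markers=markers, dosage=dosage)


def simulate_phenotypes(
    cohort: GenotypeCohort,
    config: SimulationConfig,
    carrier_block: str = "nebl_proximal",
    staging: StagingConfig = StagingConfig(),
) -> list[EchoRecord]:
    """Draw phenotypes with genotype-dependent mean and variance.

    Carriers (dogs with at least one wild-type allele at the carrier
    block's first marker) get the carrier effect and carrier SD. Raw
    measurements are back-computed so the analysis pipeline reproduces the
    simulated metrics: LA = LA:Ao x Ao, LVIDd = LVIDdN x weight^0.294.
    Murmur/CHF flags are thresholded on the simulated metrics so every
    ACVIM stage is exercised.
    """
    block = next((b for b in config.blocks if b.label == carrier_block), None)
    if block is None:
        raise ValidationError(f"carrier block {carrier_block!r} not in config")
    marker_id = f"arr{block.chrom}_{block.positions[0]}"
    dose = cohort.dosage_vector(marker_id)
    carrier = (dose != MISSING) & (dose < 2)

    rng = np.random.default_rng(config.seed + 1)
    n = cohort.n_samples
    ages = np.clip(rng.normal(*config.age_dist, size=n), 1.0, 16.0)
    weights = np.clip(rng.normal(*config.weight_dist, size=n), 4.0, 15.0)
    aos = np.clip(rng.normal(*config.ao_dist, size=n), 0.8, 2.2)
    sexes = rng.choice(["M", "F"], size=n)

    def draw(model: MetricModel) -> np.ndarray:
        sd = np.where(carrier, model.sd_carrier, model.sd_hom)
        return (
            model.intercept
            + model.age_slope * ages
            + model.carrier_effect * carrier
            + rng.normal(0.0, 1.0, size=n) * sd
        )

    la_ao = np.maximum(draw(config.la_ao_model), 0.6)
    lvidd_n = np.maximum(draw(config.lvidd_n_model), 0.6)

    records = []
    for i, sid in enumerate(cohort.sample_ids):
        murmur = la_ao[i] >= 1.3
        chf = la_ao[i] >= 2.2 and staging.enlarged(la_ao[i], lvidd_n[i])
        refractory = chf and la_ao[i] >= 3.0
        records.append(
            EchoRecord(
                dog_id=sid,
                sex=str(sexes[i]),
                age=float(ages[i]),
                weight=float(weights[i]),
                lvidd=float(lvidd_n[i] * weights[i] ** 0.294),
                la=float(la_ao[i] * aos[i]),
                ao=float(aos[i]),
                murmur=bool(murmur),
                chf=bool(chf),
                refractory=bool(refractory),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Deterministic printed-composition fixture
# ---------------------------------------------------------------------------

_FIXTURE_SEED = 20221207  # internal; the fixture is a fixed object, not a dial

#: (gene, n background markers incl. poor-call, background MAF mean, sd)
_REGION_BACKGROUND = {
    "NEBL": (85, 0.01, 0.01),
    "LPHN2": (96, 0.19, 0.18),
    "HDGFL1": (152, 0.03, 0.05),
    "SORBS2": (125, 0.14, 0.18),
    "HTR1F": (109, 0.12, 0.10),
}

#: Markers in the HTR1F region given a poor call rate (~50% missing), the
#: number disregarded by call-rate filtering in the published screen.
_N_POOR_CALL_HTR1F = 45


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(10_000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise RuntimeError("truncated normal rejection sampling failed")


def make_printed_fixture() -> tuple[GenotypeCohort, list[EchoRecord]]:
    """Deterministic cohort mirroring the published study composition.

    Genotypes: 180 dogs; wild-type heterozygotes at the predictive
    markers: 6 (three-marker proximal nebulette block, in perfect LD),
    17 (NEBL4 and NEBL5, same dogs, containing the 6), 3 (NEBL6), and
    7 het + 1 hom-ref at HDGFL1. Background markers per region are drawn
    once from fixed-seed truncated normals around the published regional
    MAF means; 45 markers in the HTR1F region carry ~50% missingness.
    Phenotypes: 178 dogs with the published stage and sex composition.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    n = 180
    sample_ids = [f"D{i + 1:03d}" for i in range(n)]

    # Carrier index sets (0-based into the 178 phenotyped dogs D001..D178;
    # D179/D180 are genotyped only and homozygous risk everywhere).
    het_nebl13 = [10, 40, 70, 100, 130, 160]
    extra_45 = [5, 20, 35, 50, 65, 80, 95, 110, 125, 140, 155]
    het_nebl45 = sorted(het_nebl13 + extra_45)  # 17 dogs, containing the 6
    het_nebl6 = [25, 85, 145]
    het_hdgfl1 = [15, 45, 75, 105, 135, 150, 165]
    homref_hdgfl1 = [60]

    markers: list[MarkerDef] = []
    cols: list[np.ndarray] = []

    def add_marker(chrom: str, pos: int, het_idx: list[int], homref_idx: list[int] | None = None,
                   missing_idx: np.ndarray | None = None) -> None:
        col = np.full(n, 2, dtype=np.int8)
        col[het_idx] = 1
        if homref_idx:
            col[homref_idx] = 0
        if missing_idx is not None:
            col[missing_idx] = MISSING
        markers.append(MarkerDef(f"arr{chrom}_{pos}", chrom, pos, "A", "G"))
        cols.append(col)

    # Predictive markers with printed heterozygote counts.
    pred = {name: (chrom, apos) for _, name, chrom, _, _, _, apos in PRINTED_VARIANTS}
    for name in ("NEBL1", "NEBL2", "NEBL3"):
        add_marker(*pred[name], het_nebl13)
    add_marker(*pred["NEBL4"], het_nebl45)
    add_marker(*pred["NEBL5"], het_nebl45)
    add_marker(*pred["NEBL6"], het_nebl6)
    add_marker(*pred["HDGFL1"], het_hdgfl1, homref_hdgfl1)
    # Polymorphic-region predictive markers at their published MAFs.
    for name, maf in (("LPHN2", 0.14), ("SORBS2", 0.13), ("HTR1F", 0.27)):
        k = round(2 * n * maf)
        add_marker(*pred[name], list(rng.choice(n, size=k, replace=False)))

    # Background markers per region.
    taken = {(m.chrom, m.pos) for m in markers}
    for gene, (n_bg, maf_mean, maf_sd) in _REGION_BACKGROUND.items():
        chrom, start, end = REGION_WINDOWS[gene]
        positions = np.linspace(start + 1000, end - 1000, n_bg).astype(int)
        poor_call = set()
        if gene == "HTR1F":
            poor_call = set(rng.choice(n_bg, size=_N_POOR_CALL_HTR1F, replace=False))
        for k_idx, pos in enumerate(positions):
            pos = int(pos)
            while (chrom, pos) in taken:
                pos += 1
            taken.add((chrom, pos))
            maf = float(np.clip(rng.normal(maf_mean, maf_sd), 0.0, 0.5))
            k = round(2 * n * maf)
            het_idx = list(rng.choice(n, size=min(k, n), replace=False))
            missing_idx = None
            if k_idx in poor_call:
                missing_idx = rng.choice(n, size=n // 2, replace=False)
            add_marker(chrom, pos, het_idx, missing_idx=missing_idx)

    cohort = GenotypeCohort(
        sample_ids=sample_ids, markers=markers, dosage=np.column_stack(cols)
    )

    # --- Phenotypes: 178 dogs with the published composition -------------
    # Heterozygote group (6): stages A:1 B1:4 B2:1, sexes M:2 F:4.
    # Homozygote group (172): stages A:2 B1:91 B2:39 C:36 D:4, M:78 F:94.
    het_stages = dict(zip(het_nebl13, ["A", "B1", "B1", "B1", "B2", "B1"]))
    het_sexes = dict(zip(het_nebl13, ["M", "F", "F", "M", "F", "F"]))
    hom_idx = [i for i in range(178) if i not in het_nebl13]
    hom_stage_list = ["A"] * 2 + ["B1"] * 91 + ["B2"] * 39 + ["C"] * 36 + ["D"] * 4
    hom_sex_list = ["M"] * 78 + ["F"] * 94
    rng.shuffle(hom_stage_list)
    rng.shuffle(hom_sex_list)

    la_model = MetricModel(1.436, 0.038, -0.37, 0.63, 0.21)
    lv_model = MetricModel(1.576, 0.038, -0.26, 0.46, 0.16)
    staging = StagingConfig()

    # Carrier effects/SDs (LA:Ao, LVIDdN) by carrier class, consistent with
    # the published per-marker group summaries: proximal-block carriers are
    # smallest and tightest; mid-gene and distal carriers intermediate;
    # HDGFL1 carriers indistinguishable from risk homozygotes.
    def carrier_params(i: int) -> tuple[float, float, float, float]:
        if i in het_nebl13:
            return -0.37, 0.21, -0.26, 0.16
        if i in extra_45:
            return -0.31, 0.26, -0.15, 0.23
        if i in het_nebl6:
            return -0.21, 0.16, -0.22, 0.26
        return 0.0, la_model.sd_hom, 0.0, lv_model.sd_hom

    records: list[EchoRecord] = []
    for i in range(178):
        is_het = i in het_stages
        stage = het_stages[i] if is_het else hom_stage_list[hom_idx.index(i)]
        sex = het_sexes[i] if is_het else hom_sex_list[hom_idx.index(i)]
        la_eff, la_sd, lv_eff, lv_sd = carrier_params(i)
        age_lo = 7.0 if stage in ("A", "B1", "B2") else 5.0
        age = _truncnorm(rng, 10.0, 1.96, age_lo, 16.0)
        weight = _truncnorm(rng, 8.4, 1.4, 5.0, 13.0)
        ao = _truncnorm(rng, 1.45, 0.12, 1.0, 2.0)

        def metric(model: MetricModel, eff: float, sd: float, lo: float, hi: float) -> float:
            mean = model.intercept + model.age_slope * age + eff
            return _truncnorm(rng, mean, sd, lo, hi)

        if stage in ("B2", "C", "D"):
            la_ao = metric(la_model, la_eff, la_sd, staging.la_ao_b2_cutoff, 4.5)
            lvidd_n = metric(lv_model, lv_eff, lv_sd, staging.lvidd_n_b2_cutoff, 4.0)
        else:
            la_ao = metric(la_model, la_eff, la_sd, 0.7, staging.la_ao_b2_cutoff - 1e-3)
            lvidd_n = metric(lv_model, lv_eff, lv_sd, 0.7, 4.0)
        records.append(
            EchoRecord(
                dog_id=sample_ids[i],
                sex=sex,
                age=age,
                weight=weight,
                lvidd=lvidd_n * weight**0.294,
                la=la_ao * ao,
                ao=ao,
                murmur=stage != "A",
                chf=stage in ("C", "D"),
                refractory=stage == "D",
            )
        )
    return cohort, records
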