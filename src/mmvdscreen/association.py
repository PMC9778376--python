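"""Genotype-stratified comparison of echocardiographic severity metrics.

Dogs homozygous for the risk (derived) allele at a predictive marker or
haplotype group are compared with carriers of the wild-type (reference)
allele on age-corrected LA:Ao and LVIDdN: an F-test asks whether the
risk-homozygote group is more variable, a Welch unequal-variance t-test
whether its mean is larger. The F statistic always puts the
risk-homozygote variance in the numerator (df1 = n_hom - 1,
df2 = n_comparison - 1) and the critical value is the upper-alpha F
quantile at those degrees of freedom. No multiple-testing correction is
applied; reports state the number of tests run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import (
    AdjustedEcho,
    EchoRecord,
    GenotypeCohort,
    GroupComparison,
    HaplotypeGroup,
    Stage,
    STAGE_ORDER,
    ValidationError,
)
from .screen import round_half_away

log = logging.getLogger(__name__)

PHENOTYPES = ("la_ao_age8", "lvidd_n_age8")


def variance_f_test(
    hom_values: list[float], carrier_values: list[float], alpha: float = 0.05
) -> tuple[float, int, int, float, float]:
    """Two-sample F-test for equality of variances.

    Returns (f_stat, df1, df2, f_crit, p) with f_stat = s2_hom / s2_carrier
    (sample variances, n-1 denominators), f_crit the upper-alpha quantile
    of F(df1, df2), and a one-tailed p: P(F >= f) when f >= 1 else
    P(F <= f), mirroring the spreadsheet two-sample variance test.
    """
    x = np.asarray(hom_values, dtype=float)
    y = np.asarray(carrier_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("F-test needs at least 2 values per group")
    s2x = x.var(ddof=1)
    s2y = y.var(ddof=1)
    if s2y == 0:
        raise ValidationError("degenerate F-test: zero variance in denominator group")
    f_stat = s2x / s2y
    df1, df2 = len(x) - 1, len(y) - 1
    dist = stats.f(df1, df2)
    f_crit = float(dist.ppf(1.0 - alpha))
    p = float(dist.sf(f_stat)) if f_stat >= 1.0 else float(dist.cdf(f_stat))
    return float(f_stat), df1, df2, f_crit, p


def welch_t_test(x: list[float], y: list[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances).

    Returns (t, df, p_two_sided) with Welch-Satterthwaite degrees of
    freedom; t is signed by mean(x) - mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("Welch t-test needs at least 2 values per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValidationError("degenerate t-test: both group variances are zero")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class GenotypeGroups:
    """Sample-id partition at a marker or haplotype group."""

    hom_risk: list[str]
    het: list[str]
    hom_ref: list[str]


def stratify_by_genotype(
    cohort: GenotypeCohort, target: str | HaplotypeGroup
) -> GenotypeGroups:
    """Partition genotyped samples by dosage at a marker or haplotype.

    For a haplotype group the representative marker's genotypes are used
    (members are in perfect LD by construction, so any member agrees).
    Dosage 2 = homozygous for the risk (alternate) allele; 1 = heterozygous
    carrier of the wild-type allele; 0 = homozygous wild-type.
    """
    marker_id = target.representative if isinstance(target, HaplotypeGroup) else target
    d = cohort.dosage_vector(marker_id)
    ids = np.asarray(cohort.sample_ids)
    return GenotypeGroups(
        hom_risk=list(ids[d == 2]),
        het=list(ids[d == 1]),
        hom_ref=list(ids[d == 0]),
    )


def compare_by_genotype(
    cohort: GenotypeCohort,
    adjusted: list[AdjustedEcho],
    target: str | HaplotypeGroup,
    phenotype: str,
    grouping: str = "het_only",
    alpha: float = 0.05,
) -> GroupComparison:
    """Risk-homozygote vs wild-type-carrier comparison for one phenotype.

    ``grouping="het_only"`` compares heterozygotes only (homozygous-
    reference dogs are left out of the comparison group, mirroring their
    separate handling in report tables); ``"carriers"`` pools het and
    hom-ref dogs. Groups with fewer than 2 phenotyped dogs skip the tests
    with a recorded reason.
    """
    if phenotype not in PHENOTYPES:
        raise ValidationError(f"unknown phenotype {phenotype!r}")
    if grouping not in ("het_only", "carriers"):
        raise ValidationError(f"unknown grouping policy {grouping!r}")
    groups = stratify_by_genotype(cohort, target)
    values = {a.dog_id: getattr(a, phenotype) for a in adjusted}
    hom = [values[s] for s in groups.hom_risk if s in values]
    comp_ids = groups.het if grouping == "het_only" else groups.het + groups.hom_ref
    comp = [values[s] for s in comp_ids if s in values]
    name = target.group_id if isinstance(target, HaplotypeGroup) else target

    base = dict(
        marker_or_group=name,
        phenotype_name=phenotype,
        n_hom_risk=len(hom),
        n_carrier=len(comp),
        mean_hom=float(np.mean(hom)) if hom else float("nan"),
        sd_hom=float(np.std(hom, ddof=1)) if len(hom) > 1 else float("nan"),
        mean_carrier=float(np.mean(comp)) if comp else float("nan"),
        sd_carrier=float(np.std(comp, ddof=1)) if len(comp) > 1 else float("nan"),
    )
    if len(hom) < 2 or len(comp) < 2:
        reason = f"group too small (n_hom={len(hom)}, n_comparison={len(comp)})"
        log.info("comparison at %s skipped: %s", name, reason)
        return GroupComparison(
            **base,
            f_stat=float("nan"), df1=max(len(hom) - 1, 0), df2=max(len(comp) - 1, 0),
            f_crit=float("nan"), f_p=float("nan"),
            t_stat=float("nan"), t_df=float("nan"), t_p=float("nan"),
            skipped_reason=reason,
        )
    f_stat, df1, df2, f_crit, f_p = variance_f_test(hom, comp, alpha)
    t_stat, t_df, t_p = welch_t_test(hom, comp)
    return GroupComparison(
        **base,
        f_stat=f_stat, df1=df1, df2=df2, f_crit=f_crit, f_p=f_p,
        t_stat=t_stat, t_df=t_df, t_p=t_p,
    )


def summarize_cohort(
    records: list[EchoRecord],
    adjusted: list[AdjustedEcho],
    groups: dict[str, list[str]],
) -> dict[str, dict]:
    """Per-group cohort composition and metric summaries.

    ``groups`` maps group label -> dog ids. Each summary holds n, sex
    counts, stage counts with whole-percent shares (rounded half away from
    zero), the share of dogs at stage B2 or above, and mean +/- SD of age
    and both age-corrected metrics. Ids present in ``groups`` but absent
    from the phenotype records raise a reconciliation error listing them.
    """
    rec_by_id = {r.dog_id: r for r in records}
    adj_by_id = {a.dog_id: a for a in adjusted}
    out: dict[str, dict] = {}
    for label, ids in groups.items():
        orphans = [i for i in ids if i not in rec_by_id or i not in adj_by_id]
        if orphans:
            raise ValidationError(f"group {label!r}: ids without phenotype records: {orphans}")
        rs = [rec_by_id[i] for i in ids]
        ads = [adj_by_id[i] for i in ids]
        n = len(ids)
        stage_counts = {s: sum(1 for a in ads if a.stage == s) for s in Stage}
        b2_up = sum(c for s, c in stage_counts.items() if STAGE_ORDER[s] >= STAGE_ORDER[Stage.B2])
        summary = {
            "n": n,
            "n_male": sum(1 for r in rs if r.sex == "M"),
            "n_female": sum(1 for r in rs if r.sex == "F"),
            "stage_counts": {s.value: c for s, c in stage_counts.items()},
            "stage_pct": {
                s.value: round_half_away(100.0 * c / n, 0) if n else 0.0
                for s, c in stage_counts.items()
            },
            "n_b2_or_above": b2_up,
            "pct_b2_or_above": round_half_away(100.0 * b2_up / n, 0) if n else 0.0,
        }
        for key, vals in (
            ("age", [r.age for r in rs]),
            ("la_ao_age8", [a.la_ao_age8 for a in ads]),
            ("lvidd_n_age8", [a.lvidd_n_age8 for a in ads]),
        ):
            summary[f"mean_{key}"] = float(np.mean(vals)) if vals else float("nan")
            summary[f"sd_{key}"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        out[label] = summary
    return out
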