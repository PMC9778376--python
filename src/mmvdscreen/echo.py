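"""Echocardiographic severity metrics: normalization, age-correction, staging.

Left-ventricular internal diameter in diastole is made weight-independent
by allometric scaling, LVIDdN = LVIDd / BW^0.294 (cm, kg), and left atrial
enlargement is expressed as the LA-to-aortic-root ratio LA:Ao. Because both
metrics drift upward with age in an aging screening cohort, each is
re-centred to a reference age (8 years) by a regression-based correction:
an ordinary-least-squares line of metric on age supplies the expected
value at any age, and each dog keeps its deviation from that line added to
the expected value at the reference age.
"""

from __future__ import annotations

from scipy import stats

from .model import EchoRecord, RegressionFit, Stage, StagingConfig, ValidationError

#: Allometric exponent relating LV diameter to body weight in dogs.
LVIDD_WEIGHT_EXPONENT = 0.294

#: Reference age (years) that corrected metrics are reported at.
DEFAULT_TARGET_AGE = 8.0


def normalize_lvidd(lvidd: float, weight: float) -> float:
    """Weight-normalised LVIDd: lvidd / weight**0.294."""
    if lvidd <= 0 or weight <= 0:
        raise ValidationError(f"lvidd and weight must be > 0, got {lvidd}, {weight}")
    return lvidd / weight**LVIDD_WEIGHT_EXPONENT


def la_ao_ratio(la: float, ao: float) -> float:
    """Left-atrium to aortic-root diameter ratio."""
    if la <= 0 or ao <= 0:
        raise ValidationError(f"la and ao must be > 0, got {la}, {ao}")
    return la / ao


def fit_age_regression(
    values: list[float], ages: list[float], target_age: float = DEFAULT_TARGET_AGE
) -> RegressionFit:
    """OLS fit of a metric on age, evaluated at the reference age."""
    if len(values) != len(ages):
        raise ValidationError("values and ages differ in length")
    if len(values) < 3:
        raise ValidationError("age regression needs at least 3 points")
    if len(set(ages)) < 2:
        raise ValidationError("age regression needs at least 2 distinct ages")
    res = stats.linregress(ages, values)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept), target_age=target_age)


def age_adjust(observed: float, age: float, fit: RegressionFit) -> float:
    """Correct an observation to the reference age.

    adjusted = expected(target_age) + (observed - expected(age)); the dog's
    deviation from the age trend is preserved, only the baseline moves.
    """
    return fit.expected_at_target + (observed - fit.predict(age))


def adjust_cohort(
    records: list[EchoRecord],
    target_age: float = DEFAULT_TARGET_AGE,
    staging: StagingConfig = StagingConfig(),
    stage_on_adjusted: bool = False,
    shared_fit: bool = False,
) -> tuple[list["AdjustedEcho"], RegressionFit, RegressionFit]:
    """Normalize, age-correct and stage a whole cohort.

    Each metric is corrected with its own OLS age fit by default
    (``shared_fit=True`` forces the LA:Ao coefficients onto LVIDdN for
    callers reproducing a single-equation workflow). Staging uses the raw
    metrics unless ``stage_on_adjusted`` is set; group statistics should
    use the age-corrected columns either way.
    """
    from .model import AdjustedEcho

    ages = [r.age for r in records]
    la_ao = [la_ao_ratio(r.la, r.ao) for r in records]
    lvidd_n = [normalize_lvidd(r.lvidd, r.weight) for r in records]
    fit_la = fit_age_regression(la_ao, ages, target_age)
    fit_lv = fit_la if shared_fit else fit_age_regression(lvidd_n, ages, target_age)
    adjusted = []
    for r, raw_la, raw_lv in zip(records, la_ao, lvidd_n):
        la8 = age_adjust(raw_la, r.age, fit_la)
        lv8 = age_adjust(raw_lv, r.age, fit_lv)
        stage = assign_stage(
            r,
            la8 if stage_on_adjusted else raw_la,
            lv8 if stage_on_adjusted else raw_lv,
            staging,
        )
        adjusted.append(
            AdjustedEcho(
                dog_id=r.dog_id,
                la_ao=raw_la,
                lvidd_n=raw_lv,
                la_ao_age8=la8,
                lvidd_n_age8=lv8,
                stage=stage,
            )
        )
    return adjusted, fit_la, fit_lv


def assign_stage(
    record: EchoRecord,
    la_ao: float,
    lvidd_n: float,
    config: StagingConfig = StagingConfig(),
) -> Stage:
    """ACVIM stage from clinical flags plus enlargement cutoffs.

    D: refractory CHF. C: CHF. B2: murmur with enlargement per the config
    cutoffs. B1: murmur without enlargement. A: at risk, no murmur.
    """
    if record.chf and record.refractory:
        return Stage.D
    if record.chf:
        return Stage.C
    if record.murmur:
        return Stage.B2 if config.enlarged(la_ao, lvidd_n) else Stage.B1
    return Stage.A
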