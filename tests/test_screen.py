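"""Fixation screen: frequency math, region classification, marker selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmvdscreen import (
    MISSING,
    GenotypeCohort,
    MarkerDef,
    RiskVariant,
    ValidationError,
    classify_region,
    extract_region,
    filter_call_rate,
    genotype_counts,
    minor_allele_frequency,
    select_predictive_marker,
)
from mmvdscreen.model import GenotypeCounts
from mmvdscreen.screen import round_half_away


def _cohort_from_column(dosages):
    d = np.asarray(dosages, dtype=np.int8).reshape(-1, 1)
    return GenotypeCohort(
        sample_ids=[f"s{i}" for i in range(len(dosages))],
        markers=[MarkerDef("m", "1", 100, "A", "G")],
        dosage=d,
    )


class TestGenotypeCounts:
    def test_fixture_nebl3_counts(self, printed_cohort):
        cohort, _ = printed_cohort
        counts = genotype_counts(cohort, "arr2_11979724")
        assert (counts.n_hom_ref, counts.n_het, counts.n_hom_alt, counts.n_missing) == (0, 6, 174, 0)

    def test_all_missing_marker(self):
        counts = genotype_counts(_cohort_from_column([MISSING] * 5), "m")
        assert (counts.n_hom_ref, counts.n_het, counts.n_hom_alt, counts.n_missing) == (0, 0, 0, 5)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=20))
    def test_counts_match_brute_force_tally_and_partition(self, dosages):
        counts = genotype_counts(_cohort_from_column(dosages), "m")
        assert counts.n_hom_ref == dosages.count(0)
        assert counts.n_het == dosages.count(1)
        assert counts.n_hom_alt == dosages.count(2)
        assert counts.total == len(dosages)


class TestMinorAlleleFrequency:
    @pytest.mark.parametrize(
        "counts, maf, minor_is_ref",
        [
            (GenotypeCounts(0, 6, 174, 0), 6 / 360, True),  # near-fixed risk allele
            (GenotypeCounts(0, 0, 50, 0), 0.0, True),  # monomorphic: ref absent, hence minor
            (GenotypeCounts(0, 9, 0, 0), 0.5, False),  # maximal MAF, alt is minor
        ],
    )
    def test_frequency_and_minor_identity(self, counts, maf, minor_is_ref):
        got_maf, got_ref = minor_allele_frequency(counts)
        assert got_maf == pytest.approx(maf, abs=1e-12)
        assert got_ref is minor_is_ref

    def test_zero_called_genotypes_is_an_error(self):
        with pytest.raises(ValidationError):
            minor_allele_frequency(GenotypeCounts(0, 0, 0, 10))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.tuples(
            st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
        ).filter(lambda t: sum(t) > 0)
    )
    def test_maf_invariant_under_ref_alt_swap(self, triple):
        a, b, c = triple
        maf1, _ = minor_allele_frequency(GenotypeCounts(a, b, c, 0))
        maf2, _ = minor_allele_frequency(GenotypeCounts(c, b, a, 0))
        assert maf1 == pytest.approx(maf2, abs=1e-12)
        assert 0.0 <= maf1 <= 0.5

    def test_reported_rounding_half_away_from_zero(self):
        # 9/360 = 0.025 must report as 0.03, not banker's 0.02
        assert round_half_away(9 / 360, 2) == 0.03
        assert round_half_away(0.0166, 2) == 0.02


class TestCallRateFilter:
    def test_constructed_low_call_markers_are_exactly_the_dropped_set(self):
        rng = np.random.default_rng(3)
        n, m = 40, 10
        dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        forced = [2, 5, 9]
        for j in forced:
            dosage[: n // 2, j] = MISSING  # 50% call rate
        cohort = GenotypeCohort(
            sample_ids=[f"s{i}" for i in range(n)],
            markers=[MarkerDef(f"m{j}", "1", 100 + j, "A", "G") for j in range(m)],
            dosage=dosage,
        )
        kept, dropped = filter_call_rate(cohort, 0.9)
        assert dropped == [f"m{j}" for j in forced]
        assert kept.n_markers == m - len(forced)

    def test_fully_called_panel_keeps_everything(self, printed_cohort):
        cohort, _ = printed_cohort
        kept, dropped = filter_call_rate(cohort, 0.9)
        assert len(dropped) == 45  # the poor-call markers built into the fixture
        assert kept.n_markers == cohort.n_markers - 45
        kept2, dropped2 = filter_call_rate(kept, 0.9)
        assert dropped2 == []


class TestExtractRegion:
    def test_closed_interval_boundaries(self):
        markers = [MarkerDef(f"m{p}", "2", p, "A", "G") for p in (100, 200, 201)]
        cohort = GenotypeCohort(
            sample_ids=["s1"], markers=markers, dosage=np.zeros((1, 3), dtype=np.int8)
        )
        sub = extract_region(cohort, "2", 100, 200)
        assert [m.marker_id for m in sub.markers] == ["m100", "m200"]

    def test_published_nebl_window_contains_all_predictive_markers(self, printed_cohort):
        cohort, _ = printed_cohort
        sub = extract_region(cohort, "2", 11_650_000, 12_650_000)
        ids = {m.marker_id for m in sub.markers}
        for pos in (11_822_980, 11_832_538, 11_979_724, 12_085_928, 12_174_951, 12_567_760):
            assert f"arr2_{pos}" in ids

    def test_empty_region_is_allowed(self, printed_cohort):
        cohort, _ = printed_cohort
        assert extract_region(cohort, "2", 1, 2).n_markers == 0


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "mafs, status",
        [
            ([0.01, 0.0, 0.02], "potential_fixation"),
            ([0.19, 0.20, 0.18], "polymorphic"),
            ([0.05, 0.05, 0.05], "polymorphic"),  # strict inequality at threshold
        ],
    )
    def test_status_from_mean(self, mafs, status):
        _, _, got = classify_region(mafs)
        assert got == status

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValidationError):
            classify_region([])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 0.5), min_size=1, max_size=20),
        st.floats(0.0, 0.04),
    )
    def test_adding_below_mean_marker_cannot_unfix(self, mafs, low):
        mean, _, status = classify_region(mafs)
        if status != "potential_fixation":
            return
        _, _, status2 = classify_region(mafs + [min(low, mean)])
        assert status2 == "potential_fixation"


class TestPredictiveMarkerSelection:
    VARIANT = RiskVariant(
        gene="NEBL", name="V", chrom="2", pos=11_979_724, allele_ref="G", allele_alt="A"
    )

    @staticmethod
    def _markers(*positions):
        return [MarkerDef(f"m{p}", "2", p, "A", "G") for p in positions]

    def test_exact_position_marker_wins(self):
        m = select_predictive_marker(self.VARIANT, self._markers(11_979_724, 11_979_800))
        assert m.pos == 11_979_724

    def test_nearest_downstream_within_limit(self):
        m = select_predictive_marker(self.VARIANT, self._markers(11_979_824, 11_984_724))
        assert m.pos == 11_979_824

    def test_distant_downstream_falls_back_upstream(self):
        # downstream marker 8001 bp away: the closer upstream marker is chosen
        m = select_predictive_marker(
            self.VARIANT, self._markers(11_977_724, 11_987_725)
        )
        assert m.pos == 11_977_724

    def test_no_marker_on_chromosome_is_an_error(self):
        with pytest.raises(ValidationError):
            select_predictive_marker(self.VARIANT, [MarkerDef("x", "5", 1, "A", "G")])
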