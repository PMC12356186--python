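"""Data model, CSV round trips, and descriptive survey statistics."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snakeroad import fielddata
from snakeroad.encounters import (
    GroupStats,
    SnakeEncounter,
    SurveyEffort,
    ValidationError,
    bin_route_positions,
    filter_adult_atrox,
    monthly_summary,
    read_encounters,
    size_range_overlap,
    species_morphometry,
    total_length,
    uniformity_chi_square,
    welch_t,
    write_encounters,
)
from conftest import make_encounter


class TestRecordValidation:
    def test_status_required(self):
        with pytest.raises(ValidationError):
            make_encounter(status="dead")

    @pytest.mark.parametrize("field,value", [
        ("svl_cm", 0.0), ("svl_cm", -1.0), ("weight_g", 0.0),
        ("tail_cm", -0.1), ("route_km", 37.5), ("route_km", -1.0),
    ])
    def test_morphometric_invariants(self, field, value):
        with pytest.raises(ValidationError):
            make_encounter(**{field: value})

    def test_missing_morphometrics_permitted(self):
        e = make_encounter()
        assert e.svl_cm is None and total_length(e) is None


class TestCsvIO:
    def test_empty_file_gives_empty_sequence(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("species,encounter_date,survey_type,status,demo_class,"
                     "svl_cm,tail_cm,weight_g,route_km,time_hhmm,impact_point\n")
        assert read_encounters(p) == []

    def test_single_row_parse(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text(
            "species,encounter_date,survey_type,status,demo_class,svl_cm,"
            "tail_cm,weight_g,route_km,time_hhmm,impact_point\n"
            "Crotalus atrox,2017-08-04,standardized,DOR,male,78.0,7.0,390,12.4,,midbody\n"
        )
        (rec,) = read_encounters(p)
        assert rec.svl_cm == 78.0
        assert rec.status == "DOR"
        assert rec.time_hhmm is None
        assert rec.impact_point == "midbody"

    def test_round_trip_preserves_fields(self, tmp_path, mixed_community):
        p = tmp_path / "rt.csv"
        write_encounters(mixed_community, p)
        assert read_encounters(p) == mixed_community

    def test_invalid_rows_reported_with_numbers(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "species,encounter_date,survey_type,status,demo_class,svl_cm,"
            "tail_cm,weight_g,route_km,time_hhmm,impact_point\n"
            "Crotalus atrox,2017-08-04,standardized,EATEN,male,,,,,,\n"
            "Crotalus atrox,2017-08-04,standardized,AOR,male,,,,,,\n"
        )
        with pytest.raises(ValidationError, match="row 1"):
            read_encounters(p)


class TestTotalLength:
    def test_published_adult_male_means(self):
        e = make_encounter(svl_cm=78.86, tail_cm=7.05)
        assert total_length(e) == pytest.approx(85.91)

    def test_zero_tail_edge(self):
        assert total_length(make_encounter(svl_cm=40.0, tail_cm=0.0)) == 40.0

    def test_missing_part_gives_missing(self):
        assert total_length(make_encounter(tail_cm=5.0)) is None


class TestAdultFilter:
    def test_strict_inequality_and_required_fields(self):
        at_cut = make_encounter(svl_cm=40.0, tail_cm=4.0, weight_g=100.0)
        above = make_encounter(svl_cm=40.1, tail_cm=4.0, weight_g=100.0)
        unweighed = make_encounter(svl_cm=90.0, tail_cm=8.0)
        other = make_encounter(species="Crotalus viridis", svl_cm=80.0,
                               tail_cm=6.0, weight_g=200.0)
        kept = filter_adult_atrox([at_cut, above, unweighed, other])
        assert kept == [above]

    def test_relaxed_size_filter_keeps_all_sizes(self):
        juv = make_encounter(demo_class="juvenile", svl_cm=30.0, tail_cm=2.5)
        adult = make_encounter(svl_cm=80.0, tail_cm=7.0)
        kept = filter_adult_atrox([juv, adult], svl_min=None, require={"svl", "tail"})
        assert kept == [juv, adult]

    def test_empty_input(self):
        assert filter_adult_atrox([]) == []

    def test_order_preserved(self, mixed_community):
        kept = filter_adult_atrox(mixed_community, svl_min=None,
                                  require={"svl", "tail", "weight"})
        assert [e.svl_cm for e in kept] == [78.0, 95.5, 33.0]


class TestMonthlySummary:
    def test_reproduces_published_2017_table(self):
        table = monthly_summary(fielddata.survey_encounters(), fielddata.survey_efforts())
        sept = table.loc["2017-09"]
        assert sept.aor_count + sept.dor_count == 25
        assert sept.snakes_per_km == pytest.approx(0.113, abs=5e-4)
        assert sept.snakes_per_visit == pytest.approx(8.3, abs=0.05)
        total = table.loc["total"]
        assert total.aor_count + total.dor_count == 101
        assert total.snakes_per_km == pytest.approx(0.057, abs=5e-4)
        assert total.pct_dor == pytest.approx(35.6, abs=0.05)

    def test_no_dor_month_edge(self):
        es = [make_encounter(), make_encounter()]
        fs = [SurveyEffort(date(2017, 8, 5), "standardized", 74.0)]
        row = monthly_summary(es, fs).loc["2017-08"]
        assert row.pct_dor == 0.0
        assert math.isnan(row.aor_dor_ratio)

    def test_month_without_effort_errors(self):
        es = [make_encounter(encounter_date=date(2017, 7, 1))]
        fs = [SurveyEffort(date(2017, 8, 5), "standardized", 74.0)]
        with pytest.raises(ValueError, match="no recorded effort"):
            monthly_summary(es, fs)

    def test_counts_conserved(self, mixed_community, efforts_aug_sep):
        table = monthly_summary(mixed_community, efforts_aug_sep)
        months = table.drop(index="total")
        assert (months.aor_count.sum() + months.dor_count.sum()) == len(mixed_community)
        assert ((table.pct_dor.dropna() >= 0) & (table.pct_dor.dropna() <= 100)).all()


class TestRouteBinning:
    def test_eighteen_bins_with_merged_remainder(self):
        counts, edges, skipped = bin_route_positions(
            [make_encounter(route_km=0.5)])
        assert len(counts) == 18
        assert edges[-2:] == pytest.approx([34.0, 37.0])
        assert counts[0] == 1 and counts[1:].sum() == 0 and skipped == 0

    def test_boundary_goes_to_merged_last_bin(self):
        counts, _, _ = bin_route_positions([make_encounter(route_km=36.5)])
        assert counts[-1] == 1

    def test_missing_positions_skipped_and_counted(self):
        counts, _, skipped = bin_route_positions(
            [make_encounter(), make_encounter(route_km=1.0)])
        assert counts.sum() == 1 and skipped == 1


class TestUniformityChiSquare:
    def test_equal_counts_equal_widths(self):
        stat, df, p = uniformity_chi_square([5, 5, 5], [2, 2, 2])
        assert stat == 0.0 and df == 2 and p == pytest.approx(1.0)

    def test_hand_computed_two_bins(self):
        stat, df, _ = uniformity_chi_square([10, 0], [1, 1])
        assert stat == pytest.approx(10.0) and df == 1

    def test_width_proportional_expectation(self):
        stat, _, _ = uniformity_chi_square([4, 4, 2], [2, 2, 1])
        assert stat == pytest.approx(0.0)

    def test_uniform_histogram_from_binning(self):
        # 10 snakes per km of route -> exactly width-proportional counts
        es = [make_encounter(route_km=min(km + 0.05, 37.0))
              for km in np.arange(0, 37, 0.1)]
        counts, edges, _ = bin_route_positions(es)
        stat, _, p = uniformity_chi_square(counts, np.diff(edges))
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    @given(st.lists(st.integers(0, 40), min_size=2, max_size=10).filter(lambda c: sum(c) > 0))
    def test_matches_brute_force_oracle(self, counts):
        widths = np.ones(len(counts))
        stat, df, _ = uniformity_chi_square(counts, widths)
        exp = sum(counts) / len(counts)
        brute = sum((c - exp) ** 2 / exp for c in counts)
        assert stat == pytest.approx(brute, rel=1e-12)
        assert df == len(counts) - 1

    def test_zero_width_bin_rejected(self):
        with pytest.raises(ValueError):
            uniformity_chi_square([1, 1], [1, 0])


class TestMorphometry:
    def test_group_of_one(self):
        table = species_morphometry([make_encounter(svl_cm=52.3, tail_cm=14.1)])
        row = table[table.demo_class == "male"].iloc[0]
        assert np.isnan(row.svl_sd) and row.svl_min == row.svl_max == 52.3

    def test_pct_dor_includes_unmeasured(self, mixed_community):
        table = species_morphometry(mixed_community)
        ae = table[(table.species == "Arizona elegans") & (table.demo_class == "overall")]
        # one measured AOR female + one unmeasured DOR -> 50% DOR over both
        assert ae.iloc[0].pct_dor == pytest.approx(50.0)
        assert ae.iloc[0].svl_n == 1

    def test_all_missing_trait_left_missing(self):
        table = species_morphometry([make_encounter(demo_class="unknown")])
        assert np.isnan(table.iloc[0].svl_mean)


class TestWelchT:
    def test_published_female_length_df(self):
        # DOR vs AOR female total length; the printed t is not
        # reproducible from the printed summaries, the df is
        dor = GroupStats(n=5, mean=83.7, sd=3.40, min=79.8, max=87.6)
        aor = GroupStats(n=11, mean=68.81, sd=16.19, min=47.3, max=91.7)
        _, df, _ = welch_t(dor, aor)
        assert round(df) == 12

    def test_identical_groups(self):
        g = GroupStats(n=5, mean=10.0, sd=2.0, min=7, max=13)
        t, _, p = welch_t(g, g)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_small_case(self):
        a = GroupStats(n=2, mean=1.0, sd=1.0, min=0, max=2)
        b = GroupStats(n=2, mean=3.0, sd=1.0, min=2, max=4)
        t, df, _ = welch_t(a, b)
        assert t == pytest.approx(-2.0) and df == pytest.approx(2.0)

    @given(
        st.floats(-100, 100), st.floats(-100, 100),
        st.floats(0.1, 50), st.floats(0.1, 50),
        st.integers(2, 40), st.integers(2, 40),
        st.floats(0.01, 100),
    )
    def test_antisymmetric_and_scale_invariant(self, ma, mb, sa, sb, na, nb, c):
        a = GroupStats(n=na, mean=ma, sd=sa, min=ma - sa, max=ma + sa)
        b = GroupStats(n=nb, mean=mb, sd=sb, min=mb - sb, max=mb + sb)
        t_ab, df_ab, _ = welch_t(a, b)
        t_ba, df_ba, _ = welch_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert df_ab == pytest.approx(df_ba)
        a_sc = GroupStats(n=na, mean=c * ma, sd=c * sa, min=c * (ma - sa), max=c * (ma + sa))
        b_sc = GroupStats(n=nb, mean=c * mb, sd=c * sb, min=c * (mb - sb), max=c * (mb + sb))
        t_sc, _, _ = welch_t(a_sc, b_sc)
        assert t_sc == pytest.approx(t_ab, rel=1e-9, abs=1e-9)

    def test_requires_sd(self):
        a = GroupStats(n=3, mean=1.0, sd=None, min=1, max=1)
        b = GroupStats(n=3, mean=2.0, sd=1.0, min=1, max=3)
        with pytest.raises(ValueError):
            welch_t(a, b)


class TestSizeRanges:
    def test_per_species_status_ranges(self, mixed_community):
        table = size_range_overlap(mixed_community)
        atrox_dor = table[(table.species == "Crotalus atrox") & (table.status == "DOR")]
        assert atrox_dor.iloc[0].n == 1
        assert atrox_dor.iloc[0].svl_min == 95.5

    def test_single_status_reports_other_empty(self):
        table = size_range_overlap([make_encounter(svl_cm=50.0)])
        dor = table[table.status == "DOR"].iloc[0]
        assert dor.n == 0 and np.isnan(dor.svl_min)
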