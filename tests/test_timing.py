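import pytest
from hypothesis import given, settings, strategies as st

from chronodiet.intake import UndefinedMetricError
from chronodiet.recall_data import EatingOccasion, RecallDay, OCCASION_LABELS
from chronodiet.timing import (
    TimingThresholds,
    classify_after_2000,
    classify_early_eater,
    largest_meal,
    lunch_consistency,
    mean_occasion_times,
    pct_energy_before,
    timing_profile,
)

from conftest import make_day

TH = TimingThresholds()


class TestPctEnergyBefore:
    def test_all_before_cutoff(self):
        d1 = make_day("S1", 1, [("breakfast", "09:00", 500.0)])
        d2 = make_day("S1", 2, [("breakfast", "09:30", 700.0)])
        assert pct_energy_before(d1, d2, 960) == 100.0

    def test_start_exactly_at_cutoff_excluded(self):
        d1 = make_day("S1", 1, [("lunch", "16:00", 500.0)])
        d2 = make_day("S1", 2, [("lunch", "16:00", 500.0)])
        assert pct_energy_before(d1, d2, 960) == 0.0

    def test_pooled_hand_example(self):
        occ = [("breakfast", "09:00", 600.0), ("dinner", "20:00", 400.0)]
        d1, d2 = make_day("S1", 1, occ), make_day("S1", 2, occ)
        assert pct_energy_before(d1, d2, 960) == pytest.approx(60.0)

    def test_pooled_vs_per_day_mean(self):
        d1 = make_day("S1", 1, [("breakfast", "09:00", 900.0),
                                ("dinner", "20:00", 100.0)])
        d2 = make_day("S1", 2, [("breakfast", "09:00", 100.0),
                                ("dinner", "20:00", 900.0)])
        pooled = pct_energy_before(d1, d2, 960, method="pooled")
        per_day = pct_energy_before(d1, d2, 960, method="per_day_mean")
        assert pooled == pytest.approx(50.0)
        assert per_day == pytest.approx(50.0)  # symmetric case agrees
        d2b = make_day("S1", 2, [("breakfast", "09:00", 100.0),
                                 ("dinner", "20:00", 400.0)])
        assert pct_energy_before(d1, d2b, 960, "pooled") != pytest.approx(
            pct_energy_before(d1, d2b, 960, "per_day_mean")
        )

    def test_zero_energy_undefined(self):
        d = make_day("S1", 1, [("lunch", "12:00", 0.0)])
        with pytest.raises(UndefinedMetricError):
            pct_energy_before(d, d, 960)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(OCCASION_LABELS),
                st.integers(min_value=0, max_value=1439),
                st.floats(min_value=1.0, max_value=2000.0),
            ),
            min_size=1, max_size=8, unique_by=lambda t: t[0],
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_cutoff_and_100_at_midnight(self, triples):
        occ = tuple(EatingOccasion(l, t, energy=e) for l, t, e in triples)
        d1 = RecallDay("S1", 1, occ)
        d2 = RecallDay("S1", 2, occ)
        values = [pct_energy_before(d1, d2, c) for c in (240, 720, 960, 1200, 1440)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(100.0)


class TestEaterClassifications:
    @pytest.mark.parametrize("pct,expected", [(60.0, True), (59.99, False),
                                              (75.0, True), (100.0, True)])
    def test_early_eater_inclusive_threshold(self, pct, expected):
        assert classify_early_eater(pct, TH) is expected

    def test_after_2000_strict_boundary(self):
        d = make_day("S1", 1, [("dinner", "20:00", 500.0)])
        assert classify_after_2000(d, d, TH) is False

    def test_after_2000_any_day(self):
        d1 = make_day("S1", 1, [("dinner", "19:00", 500.0)])
        d2 = make_day("S1", 2, [("dinner", "19:00", 500.0),
                                ("after_dinner_snack", "22:30", 80.0)])
        assert classify_after_2000(d1, d2, TH) is True
        assert classify_after_2000(d1, d1, TH) is False

    def test_after_2000_monotone_under_added_late_occasion(self):
        d1 = make_day("S1", 1, [("lunch", "15:00", 600.0)])
        d2 = make_day("S1", 2, [("lunch", "15:30", 600.0)])
        assert classify_after_2000(d1, d2, TH) is False
        d2_late = make_day("S1", 2, [("lunch", "15:30", 600.0),
                                     ("dinner", "21:00", 300.0)])
        assert classify_after_2000(d1, d2_late, TH) is True


class TestLargestMeal:
    def test_dominant_lunch(self):
        d1 = make_day("S1", 1, [("breakfast", "09:00", 400.0),
                                ("lunch", "15:00", 800.0)])
        d2 = make_day("S1", 2, [("breakfast", "09:00", 350.0),
                                ("lunch", "15:30", 820.0)])
        labels, mean_t = largest_meal(d1, d2)
        assert labels == ("lunch", "lunch")
        assert mean_t == pytest.approx(915.0)  # 15:15

    def test_tie_broken_by_earliest_start(self):
        d = make_day("S1", 1, [("breakfast", "09:00", 500.0),
                               ("dinner", "20:00", 500.0)])
        labels, mean_t = largest_meal(d, d)
        assert labels == ("breakfast", "breakfast")
        assert mean_t == pytest.approx(540.0)

    def test_differing_days_mean_time(self):
        d1 = make_day("S1", 1, [("lunch", "15:00", 900.0),
                                ("dinner", "20:30", 400.0)])
        d2 = make_day("S1", 2, [("lunch", "15:00", 400.0),
                                ("dinner", "20:30", 900.0)])
        labels, mean_t = largest_meal(d1, d2)
        assert labels == ("lunch", "dinner")
        assert mean_t == pytest.approx((900 + 1230) / 2)  # 17:45

    def test_snack_can_be_largest(self):
        d = make_day("S1", 1, [("lunch", "15:00", 300.0),
                               ("afternoon_snack_1", "17:00", 600.0)])
        labels, _ = largest_meal(d, d)
        assert labels == ("afternoon_snack_1", "afternoon_snack_1")

    def test_largest_dominates_all_occasions(self, small_cohort):
        for sid in list(small_cohort.subjects)[:20]:
            d1, d2 = small_cohort.days_for(sid)
            (l1, l2), _ = largest_meal(d1, d2)
            for day, lab in ((d1, l1), (d2, l2)):
                best = day.occasion(lab).energy
                assert all(best >= o.energy for o in day.occasions)


class TestMeanOccasionTimes:
    def test_mean_of_both_days(self):
        d1 = make_day("S1", 1, [("lunch", "15:00", 700.0)])
        d2 = make_day("S1", 2, [("lunch", "15:30", 700.0)])
        assert mean_occasion_times(d1, d2)["lunch"] == pytest.approx(915.0)

    def test_single_day_label(self):
        d1 = make_day("S1", 1, [("lunch", "15:00", 700.0),
                                ("morning_snack", "11:00", 150.0)])
        d2 = make_day("S1", 2, [("lunch", "15:00", 700.0)])
        times = mean_occasion_times(d1, d2)
        assert times["morning_snack"] == pytest.approx(660.0)

    def test_absent_labels_not_reported(self):
        d = make_day("S1", 1, [("breakfast", "09:00", 400.0),
                               ("lunch", "15:00", 700.0)])
        assert set(mean_occasion_times(d, d)) == {"breakfast", "lunch"}


class TestLunchConsistency:
    @pytest.mark.parametrize(
        "t1,t2,gap,within",
        [("15:00", "15:24", 24, True), ("13:00", "14:00", 60, True),
         ("12:00", "16:30", 270, False)],
    )
    def test_gap_and_flag(self, t1, t2, gap, within):
        d1 = make_day("S1", 1, [("lunch", t1, 700.0)])
        d2 = make_day("S1", 2, [("lunch", t2, 700.0)])
        g, w = lunch_consistency(d1, d2)
        assert g == gap
        assert w is within

    def test_missing_lunch_flagged(self):
        d1 = make_day("S1", 1, [("lunch", "15:00", 700.0)])
        d2 = make_day("S1", 2, [("dinner", "20:00", 700.0)])
        assert lunch_consistency(d1, d2) == (None, None)


class TestTimingProfile:
    def test_profile_consistency(self):
        d1 = make_day("S1", 1, [("breakfast", "09:00", 600.0),
                                ("lunch", "15:00", 800.0),
                                ("dinner", "20:30", 400.0)])
        d2 = make_day("S1", 2, [("breakfast", "09:00", 600.0),
                                ("lunch", "15:24", 800.0),
                                ("dinner", "19:30", 400.0)])
        p = timing_profile(d1, d2)
        assert p.pct_energy_before_cutoff == pytest.approx(
            100 * 2800 / 3600
        )
        assert p.early_eater is (p.pct_energy_before_cutoff >= 60)
        assert p.eats_after_2000 is True  # 20:30 on day 1
        assert p.lunch_day_gap == 24
        assert p.occasions_per_day == 3.0
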