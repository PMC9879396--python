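import statistics
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from windcurtail import datasets
from windcurtail.identification import (
    ConfusionCounts,
    TimePeriod,
    UndefinedRateError,
    accuracy_rate,
    build_confusion,
    cross_period_summary,
    counts_to_frame,
    false_negative_rate,
    false_positive_rate,
    frame_to_counts,
    load_periods,
    dump_periods,
    read_counts_csv,
    write_counts_csv,
)
from windcurtail.records import EAGLE, NO_IMAGE, NON_EAGLE

from conftest import make_record, make_track


class TestTimePeriod:
    def test_reversed_dates_rejected(self):
        with pytest.raises(ValueError):
            TimePeriod("p", "2021-02-01", "2021-01-01")

    def test_excluded_outside_rejected(self):
        with pytest.raises(ValueError):
            TimePeriod("p", "2021-01-01", "2021-01-31", (("2021-02-01", "2021-02-02"),))

    def test_contains_respects_exclusions(self):
        p = TimePeriod("p", "2021-01-01", "2021-01-31", (("2021-01-10", "2021-01-12"),))
        assert p.contains(date(2021, 1, 9))
        assert not p.contains(date(2021, 1, 11))
        assert not p.contains(date(2021, 2, 1))

    def test_n_days_with_exclusion(self):
        # 58 inclusive days minus an 18-day excluded range
        p = TimePeriod("p", "2019-02-27", "2019-04-25", (("2019-04-02", "2019-04-19"),))
        assert p.n_days == 40

    def test_periods_yaml_roundtrip(self, tmp_path):
        periods = datasets.load_study_periods()
        dump_periods(periods, tmp_path / "periods.yaml")
        assert load_periods(tmp_path / "periods.yaml") == periods


class TestBuildConfusion:
    def test_small_fixture(self, periods):
        import datetime as dt

        def track(tid, det, labels, day=15):
            recs = [
                make_record(
                    tid,
                    t=dt.datetime(2021, 1, day, 12, 0, i, tzinfo=dt.timezone.utc),
                    label=lab,
                )
                for i, lab in enumerate(labels)
            ]
            return make_track(recs, determination=det)

        tracks = [
            track("a", EAGLE, [EAGLE, EAGLE, NON_EAGLE]),
            track("b", NON_EAGLE, [EAGLE, NON_EAGLE]),
            track("c", NO_IMAGE, [EAGLE]),
            track("d", EAGLE, [EAGLE], day=20),
        ]
        counts = build_confusion(tracks, periods)
        assert counts["p1"] == ConfusionCounts(
            eagle_correct=3,
            eagle_as_noneagle=1,
            noneagle_as_eagle=1,
            noneagle_correct=1,
            noimage_as_eagle=1,
        )

    def test_empty_input(self, periods):
        assert build_confusion([], periods) == {}

    def test_permutation_invariance(self, periods, rng):
        import datetime as dt

        tracks = []
        for i in range(20):
            det = [EAGLE, NON_EAGLE, NO_IMAGE][i % 3]
            recs = [
                make_record(
                    f"t{i}",
                    t=dt.datetime(2021, 1 + (i % 2), 15, 10, 0, s, tzinfo=dt.timezone.utc),
                    label=EAGLE if (i + s) % 2 else NON_EAGLE,
                )
                for s in range(5)
            ]
            tracks.append(make_track(recs, determination=det))
        base = build_confusion(tracks, periods)
        shuffled = list(tracks)
        rng.shuffle(shuffled)
        assert build_confusion(shuffled, periods) == base

    def test_overlapping_periods_rejected(self):
        periods = [TimePeriod("a", "2021-01-01", "2021-01-20"), TimePeriod("b", "2021-01-15", "2021-01-30")]
        with pytest.raises(ValueError, match="overlap"):
            build_confusion([], periods)

    def test_gap_records_dropped(self, periods):
        import datetime as dt

        t = make_track(
            [make_record("a", t=dt.datetime(2022, 6, 1, tzinfo=dt.timezone.utc))],
            determination=EAGLE,
        )
        assert build_confusion([t], periods) == {}

    def test_tower_stratification_adds_up(self, periods):
        import datetime as dt

        tracks = []
        for i, tower in enumerate(["c1", "c2", "c1"]):
            recs = [
                make_record(
                    f"t{i}",
                    t=dt.datetime(2021, 1, 15, 10, 0, s, tzinfo=dt.timezone.utc),
                    label=EAGLE,
                    tower_id=tower,
                )
                for s in range(3)
            ]
            tracks.append(make_track(recs, determination=EAGLE))
        combined = build_confusion(tracks, periods)
        by_tower = build_confusion(tracks, periods, group_by_tower=True)
        total = sum(by_tower.values(), ConfusionCounts())
        assert total == combined["p1"]


@pytest.fixture(scope="module")
def counts():
    return datasets.load_identification_counts()


@pytest.fixture(scope="module")
def total(counts):
    return sum(counts.values(), ConfusionCounts())


class TestReferenceCounts:
    """The bundled deployment counts reproduce the published arithmetic."""

    def test_first_period_cells(self, counts):
        c = counts["original_configuration"]
        assert (
            c.eagle_correct,
            c.eagle_as_noneagle,
            c.noneagle_as_eagle,
            c.noneagle_correct,
            c.noimage_as_eagle,
            c.noimage_as_noneagle,
        ) == (3975, 394, 9362, 53200, 0, 0)

    def test_grand_totals(self, total):
        assert total.n_total == 611537
        assert total.n_eagle == 44325
        assert total.n_noneagle == 566081
        assert total.n_noimage == 1131
        assert total.n_system_eagle == 118460

    def test_overall_accuracy(self, total):
        assert accuracy_rate(total) == pytest.approx(0.846, abs=5e-4)

    def test_update_period_accuracy(self, counts):
        assert accuracy_rate(counts["system_update"]) == pytest.approx(0.938, abs=5e-4)

    def test_false_negative_rate(self, total):
        assert false_negative_rate(total) == pytest.approx(10201 / 44325)
        assert 1 - false_negative_rate(total) == pytest.approx(0.770, abs=5e-4)

    def test_false_positive_rate(self, total):
        assert false_positive_rate(total) == pytest.approx(83786 / 566081)
        assert 1 - false_positive_rate(total) == pytest.approx(0.852, abs=5e-4)

    def test_cross_period_mean_and_sd(self, counts):
        summary = cross_period_summary(counts)
        mean, sd = summary["accuracy"]
        assert mean == pytest.approx(0.860, abs=5e-4)
        assert sd == pytest.approx(0.059, abs=5e-4)

    def test_accuracy_is_weighted_combination(self, counts, total):
        for c in list(counts.values()) + [total]:
            w_e = c.n_eagle / c.n_analyzed
            combo = (1 - false_negative_rate(c)) * w_e + (1 - false_positive_rate(c)) * (1 - w_e)
            assert accuracy_rate(c) == pytest.approx(combo)

    def test_csv_roundtrip(self, counts, tmp_path):
        write_counts_csv(counts, tmp_path / "counts.csv")
        assert read_counts_csv(tmp_path / "counts.csv") == counts


class TestRates:
    def test_perfect_classifier(self):
        c = ConfusionCounts(eagle_correct=10, noneagle_correct=20)
        assert accuracy_rate(c) == 1.0
        assert false_negative_rate(c) == 0.0
        assert false_positive_rate(c) == 0.0

    def test_zero_denominators_signalled(self):
        with pytest.raises(UndefinedRateError):
            accuracy_rate(ConfusionCounts(noimage_as_eagle=5))
        with pytest.raises(UndefinedRateError):
            false_negative_rate(ConfusionCounts(noneagle_correct=5))
        with pytest.raises(UndefinedRateError):
            false_positive_rate(ConfusionCounts(eagle_correct=5))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(eagle_correct=-1)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 500), st.integers(0, 500), st.integers(0, 500), st.integers(1, 500)),
            min_size=1,
            max_size=6,
        )
    )
    def test_rates_in_unit_interval_and_additive(self, cells):
        counts = [
            ConfusionCounts(eagle_correct=a, eagle_as_noneagle=b, noneagle_as_eagle=c, noneagle_correct=d)
            for a, b, c, d in cells
        ]
        total = sum(counts, ConfusionCounts())
        for c in counts + [total]:
            assert 0.0 <= accuracy_rate(c) <= 1.0
            assert 0.0 <= false_negative_rate(c) <= 1.0
            assert 0.0 <= false_positive_rate(c) <= 1.0
        assert total.n_total == sum(c.n_total for c in counts)


class TestCrossPeriodSummary:
    def test_identical_rates_sd_zero(self):
        c = ConfusionCounts(eagle_correct=9, eagle_as_noneagle=1, noneagle_as_eagle=2, noneagle_correct=8)
        summary = cross_period_summary({"a": c, "b": c, "c": c})
        for mean, sd in summary.values():
            assert sd == pytest.approx(0.0)

    def test_two_period_closed_form(self):
        c1 = ConfusionCounts(eagle_correct=8, eagle_as_noneagle=2, noneagle_as_eagle=1, noneagle_correct=9)
        c2 = ConfusionCounts(eagle_correct=5, eagle_as_noneagle=5, noneagle_as_eagle=4, noneagle_correct=6)
        a, b = accuracy_rate(c1), accuracy_rate(c2)
        mean, sd = cross_period_summary({"p1": c1, "p2": c2})["accuracy"]
        assert mean == pytest.approx((a + b) / 2)
        assert sd == pytest.approx(abs(a - b) / 2**0.5)

    def test_single_period_signalled(self):
        c = ConfusionCounts(eagle_correct=1, noneagle_correct=1)
        with pytest.raises(UndefinedRateError):
            cross_period_summary({"only": c})


def test_counts_frame_roundtrip():
    counts = datasets.load_identification_counts()
    assert frame_to_counts(counts_to_frame(counts)) == counts
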