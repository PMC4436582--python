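"""Lifespan binning, midpoint dating, recency, totals and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cram.core_model import (
    FEATURES,
    DataError,
    Dataset,
    InsufficientDataError,
    MemoryRecord,
    SubjectRecord,
    bin_scheme,
    classify_recency,
    date_memories,
    event_age_years,
    parse_age_ranges,
    read_dataset,
    total_content,
    write_dataset,
)
from cram.synthetic_cohort import CohortConfig, generate_cohort


class TestBinScheme:
    def test_bin_width_scales_with_age(self):
        s20 = bin_scheme(20)
        s40 = bin_scheme(40)
        assert s20.boundaries[0] == (0.0, 2.0)
        assert s20.width == 2.0
        assert s40.width == 2 * s20.width

    def test_unit_width_at_age_ten(self):
        assert bin_scheme(10).width == 1.0

    def test_interior_bin_boundaries(self):
        lo, hi = bin_scheme(33).boundaries[6]  # bin 7
        assert lo == pytest.approx(19.8)
        assert hi == pytest.approx(23.1)

    @pytest.mark.parametrize("bad", [0, -3])
    def test_nonpositive_age_rejected(self, bad):
        with pytest.raises(Exception):
            bin_scheme(bad)

    @settings(derandomize=True, max_examples=50)
    @given(
        age=st.floats(min_value=1.0, max_value=100.0),
        n_bins=st.integers(min_value=1, max_value=20),
    )
    def test_bins_partition_the_lifespan(self, age, n_bins):
        scheme = bin_scheme(age, n_bins)
        bounds = scheme.boundaries
        widths = [hi - lo for lo, hi in bounds]
        assert sum(widths) == pytest.approx(age)
        for (_, hi_prev), (lo_next, _) in zip(bounds, bounds[1:]):
            assert hi_prev == pytest.approx(lo_next)

    def test_recent_bins_cover_last_decade(self):
        # for a 20 year old, bins overlapping the last 10 years are 6..10
        assert bin_scheme(20).recent_bins(10) == (6, 7, 8, 9, 10)


class TestEventAge:
    def test_single_bin_midpoint(self):
        assert event_age_years((5,), 30) == pytest.approx(13.5)

    def test_last_bin_midpoint(self):
        assert event_age_years((10,), 20) == pytest.approx(19.0)

    def test_union_midpoint_for_multi_bin(self):
        assert event_age_years((4, 5), 30) == pytest.approx(12.0)

    def test_monotone_in_bin_index(self):
        ages = [event_age_years((b,), 47) for b in range(1, 11)]
        assert ages == sorted(ages)

    def test_noncontiguous_bins_rejected(self):
        with pytest.raises(DataError):
            event_age_years((2, 5), 30)

    def test_bin_out_of_range_rejected(self):
        with pytest.raises(DataError):
            event_age_years((11,), 30)


class TestRecency:
    @pytest.mark.parametrize(
        "subject_age,event_age,expected",
        [(30, 25, "Recent"), (30, 13.5, "Remote"), (18, 0.9, "Remote")],
    )
    def test_examples(self, subject_age, event_age, expected):
        assert classify_recency(subject_age, event_age) == expected

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(7)
        ages = rng.uniform(1, 90, size=10_000)
        events = ages * rng.random(10_000)
        for a, e in zip(ages, events):
            expected = "Recent" if (a - e) <= 10 else "Remote"
            assert classify_recency(a, e) == expected

    def test_event_after_present_rejected(self):
        with pytest.raises(DataError):
            classify_recency(30, 31)


class TestTotalContent:
    def test_all_zero(self):
        counts = {f: 0 for f in FEATURES}
        assert total_content(counts) == 0

    def test_hand_sum(self):
        counts = dict(zip(FEATURES, (3, 2, 4, 5, 1, 0, 2, 4)))
        assert total_content(counts) == 21

    def test_single_feature(self):
        counts = {f: 0 for f in FEATURES}
        counts["things"] = 22
        assert total_content(counts) == 22

    def test_unscored_is_absent_not_zero(self):
        memory = MemoryRecord("m", "s", (1,), None)
        with pytest.raises(InsufficientDataError):
            total_content(memory)


class TestRecords:
    def test_memory_requires_one_to_three_bins(self):
        with pytest.raises(DataError):
            MemoryRecord("m", "s", ())
        with pytest.raises(DataError):
            MemoryRecord("m", "s", (1, 2, 3, 4))

    def test_negative_count_rejected(self):
        counts = {f: 1 for f in FEATURES}
        counts["people"] = -1
        with pytest.raises(DataError):
            MemoryRecord("m", "s", (1,), counts)

    def test_subject_validation(self):
        with pytest.raises(DataError):
            SubjectRecord("s", 0)
        with pytest.raises(DataError):
            SubjectRecord("s", 30, gender="other")


class TestDatingTable:
    def test_dating_columns(self, hand_dataset):
        dated = date_memories(hand_dataset)
        m1 = dated.set_index("memory_id").loc["m1"]
        assert m1["event_age"] == pytest.approx(13.5)
        assert m1["recency"] == "Remote"
        assert m1["total_content"] == 21
        m2 = dated.set_index("memory_id").loc["m2"]
        assert m2["event_age"] == pytest.approx(30 * (6 + 8) / 20)
        assert pd.isna(m2["total_content"])


class TestCsvRoundTrip:
    def test_hand_fixture_round_trip(self, hand_dataset, tmp_path):
        write_dataset(hand_dataset, tmp_path / "s.csv", tmp_path / "m.csv")
        back = read_dataset(tmp_path / "s.csv", tmp_path / "m.csv")
        assert back.memories["bins"].tolist() == hand_dataset.memories["bins"].tolist()
        s1, m1 = hand_dataset.to_records()
        s2, m2 = back.to_records()
        assert s1 == s2
        assert m1 == m2

    def test_generated_round_trip(self, small_config, tmp_path):
        ds, _ = generate_cohort(small_config, seed=3)
        write_dataset(ds, tmp_path / "s.csv", tmp_path / "m.csv")
        back = read_dataset(tmp_path / "s.csv", tmp_path / "m.csv")
        pd.testing.assert_frame_equal(
            back.subjects.astype(str), ds.subjects.astype(str)
        )
        assert back.memories["bins"].tolist() == ds.memories["bins"].tolist()
        feats = list(FEATURES)
        pd.testing.assert_frame_equal(
            back.memories[feats], ds.memories[feats], check_dtype=False
        )

    def test_semicolon_bins_cell(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "subject_id,age_years,gender,native_speaker,test_type,condition\n"
            "s1,30,female,1,full,internet\n"
        )
        header = "memory_id,subject_id,bins,scored," + ",".join(FEATURES)
        (tmp_path / "m.csv").write_text(f"{header}\nm1,s1,7;8,0,,,,,,,,\n")
        ds = read_dataset(tmp_path / "s.csv", tmp_path / "m.csv")
        assert ds.memories["bins"].iloc[0] == (7, 8)

    def test_empty_memories_file(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "subject_id,age_years,gender,native_speaker,test_type,condition\n"
        )
        header = "memory_id,subject_id,bins,scored," + ",".join(FEATURES)
        (tmp_path / "m.csv").write_text(header + "\n")
        ds = read_dataset(tmp_path / "s.csv", tmp_path / "m.csv")
        assert ds.n_memories == 0

    @pytest.mark.parametrize(
        "row,message_part",
        [
            ("m1,s1,11,0,,,,,,,,", "bin token"),
            ("m1,s1,3,1,1,1,1,-2,1,1,1,1", "negative"),
        ],
    )
    def test_parse_errors_name_row(self, tmp_path, row, message_part):
        (tmp_path / "s.csv").write_text(
            "subject_id,age_years,gender,native_speaker,test_type,condition\n"
            "s1,30,female,1,full,internet\n"
        )
        header = "memory_id,subject_id,bins,scored," + ",".join(FEATURES)
        (tmp_path / "m.csv").write_text(f"{header}\n{row}\n")
        with pytest.raises(DataError, match=message_part):
            read_dataset(tmp_path / "s.csv", tmp_path / "m.csv")

    def test_duplicate_memory_id_rejected(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "subject_id,age_years,gender,native_speaker,test_type,condition\n"
            "s1,30,female,1,full,internet\n"
        )
        header = "memory_id,subject_id,bins,scored," + ",".join(FEATURES)
        (tmp_path / "m.csv").write_text(
            f"{header}\nm1,s1,3,0,,,,,,,,\nm1,s1,4,0,,,,,,,,\n"
        )
        with pytest.raises(DataError, match="duplicate memory_id"):
            read_dataset(tmp_path / "s.csv", tmp_path / "m.csv")

    def test_missing_column_rejected(self, tmp_path):
        (tmp_path / "s.csv").write_text("subject_id,age_years\ns1,30\n")
        (tmp_path / "m.csv").write_text("memory_id\n")
        with pytest.raises(DataError, match="missing required column"):
            read_dataset(tmp_path / "s.csv", tmp_path / "m.csv")

    def test_unknown_columns_preserved(self, hand_dataset, tmp_path):
        ds = hand_dataset.copy()
        ds.memories["note"] = ["a", "b", "c"]
        write_dataset(ds, tmp_path / "s.csv", tmp_path / "m.csv")
        back = read_dataset(tmp_path / "s.csv", tmp_path / "m.csv")
        assert back.memories["note"].tolist() == ["a", "b", "c"]


def test_parse_age_ranges():
    assert parse_age_ranges("18-25,26-45") == [(18, 25), (26, 45)]
    with pytest.raises(Exception):
        parse_age_ranges("45-18")
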