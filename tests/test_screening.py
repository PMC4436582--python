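"""Screening rules against brute-force oracles and generator ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cram.core_model import ConfigError, Dataset, FEATURES, InsufficientDataError
from cram.screening import (
    CONTENT_OUTLIER,
    DEFAULT_STRATA,
    PATTERN_SUBJECT,
    UNIFORM_VECTOR,
    apply_screening,
    flag_pattern_subjects,
    flag_uniform_memory,
    outlier_threshold,
)
from cram.synthetic_cohort import ContaminantRates, generate_cohort, inject_contaminants

from conftest import make_scored_frame


def brute_force_fence(values, multiplier=3.0):
    """Independent sort-and-scan oracle: linear-interpolation quantiles."""
    v = sorted(values)
    n = len(v)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(pos)
        frac = pos - lo
        if lo + 1 < n:
            return v[lo] + frac * (v[lo + 1] - v[lo])
        return v[lo]

    q25, q75 = quantile(0.25), quantile(0.75)
    return q75 + multiplier * (q75 - q25)


def make_dataset(vector_groups):
    """Dataset from {subject_id: (age, [vectors...])}."""
    frames, subj_rows = [], []
    i = 0
    for sid, (age, vectors) in vector_groups.items():
        df = make_scored_frame(vectors, subject_ids=[sid] * len(vectors))
        df["memory_id"] = [f"{sid}_m{j}" for j in range(len(vectors))]
        frames.append(df)
        subj_rows.append(
            {
                "subject_id": sid,
                "age_years": age,
                "gender": "female",
                "native_speaker": True,
                "test_type": "full",
                "condition": "internet",
            }
        )
        i += 1
    return Dataset(pd.DataFrame(subj_rows), pd.concat(frames, ignore_index=True))


class TestUniformFlag:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([3] * 8, True),
            ([0] * 8, True),
            ([3, 3, 3, 3, 3, 3, 3, 4], False),
        ],
    )
    def test_examples(self, counts, expected):
        assert flag_uniform_memory(counts) is expected


class TestPatternSubjects:
    def test_majority_uniform_flagged(self):
        vectors = [[2] * 8, [5] * 8, [1] * 8, [1, 2, 3, 4, 5, 6, 7, 8]]
        ds = make_dataset({"s1": (30, vectors)})
        assert flag_pattern_subjects(ds) == {"s1"}

    def test_identical_vector_flagged(self):
        vectors = [[1, 2, 3, 4, 5, 6, 7, 8]] * 5
        ds = make_dataset({"s1": (30, vectors)})
        assert flag_pattern_subjects(ds) == {"s1"}

    def test_single_uniform_among_varied_not_flagged(self):
        rng = np.random.default_rng(0)
        vectors = [list(rng.integers(0, 9, 8)) for _ in range(10)]
        vectors = [v if len(set(v)) > 1 else v[:-1] + [v[-1] + 1] for v in vectors]
        vectors.append([4] * 8)
        ds = make_dataset({"s1": (30, vectors)})
        assert flag_pattern_subjects(ds) == set()

    def test_single_memory_subject_not_identical_vector(self):
        ds = make_dataset({"s1": (30, [[1, 2, 3, 4, 5, 6, 7, 8]])})
        assert flag_pattern_subjects(ds) == set()


class TestOutlierThreshold:
    def test_constant_list_has_zero_iqr(self):
        values = [20] * 6
        fence = outlier_threshold(values)
        assert fence == 20
        assert sum(v > fence for v in values) == 0

    def test_hand_example(self):
        assert outlier_threshold([1, 2, 3, 4, 100]) == pytest.approx(10.0)

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            outlier_threshold([1, 2, 3])

    @settings(derandomize=True, max_examples=300)
    @given(
        st.lists(st.integers(min_value=0, max_value=10), min_size=4, max_size=8)
    )
    def test_matches_brute_force_oracle(self, values):
        assert outlier_threshold(values) == pytest.approx(brute_force_fence(values))


class TestApplyScreening:
    def test_clean_dataset_keeps_pattern_free(self, small_config):
        ds, _ = generate_cohort(small_config, seed=11)
        clean, report = apply_screening(ds)
        assert report.removed_counts[PATTERN_SUBJECT] == 0
        # uniform flags on clean data can only be genuine all-equal vectors
        uniform_ids = set(report.removed_ids[UNIFORM_VECTOR])
        flagged = ds.memories.loc[ds.memories["memory_id"].isin(uniform_ids)]
        for _, row in flagged.iterrows():
            assert len(set(row[list(FEATURES)])) == 1
        assert report.n_scored_input == report.n_scored_retained + report.n_removed

    def test_injected_contaminants_recovered_exactly(self, small_config):
        # fence-clean baseline with margin: pre-trim at 2*IQR so that the
        # 3*IQR screening fence cleanly separates injected extremes from the
        # natural tail
        base, _ = generate_cohort(small_config, seed=21)
        prescreened, _ = apply_screening(base, multiplier=2.0)
        rates = ContaminantRates(uniform_memory=0.01, pattern_subject=0.02, outlier=0.01)
        dirty, manifest = inject_contaminants(prescreened, rates, seed=22)
        clean, report = apply_screening(dirty)
        assert report.all_removed_ids() == set(manifest["all_memory_ids"])
        assert set(report.removed_ids[CONTENT_OUTLIER]) == set(
            manifest["outlier_memories"]
        )
        pattern_ids = {e["subject_id"] for e in manifest["pattern_subjects"]}
        assert set(report.pattern_subject_ids) == pattern_ids

    def test_screening_changes_mean_when_outliers_injected(self, small_config):
        base, _ = generate_cohort(small_config, seed=31)
        prescreened, _ = apply_screening(base)
        dirty, manifest = inject_contaminants(
            prescreened, ContaminantRates(outlier=0.02), seed=32
        )
        assert manifest["outlier_memories"]
        before = dirty.memories.loc[dirty.memories["scored"], list(FEATURES)].sum(axis=1).mean()
        clean, _ = apply_screening(dirty)
        after = clean.memories.loc[clean.memories["scored"], list(FEATURES)].sum(axis=1).mean()
        assert after < before

    def test_idempotent_on_generated_cohort(self, small_config):
        ds, _ = generate_cohort(small_config, seed=41)
        once, r1 = apply_screening(ds)
        twice, r2 = apply_screening(once)
        assert r2.n_removed == 0
        pd.testing.assert_frame_equal(
            once.memories[list(FEATURES)], twice.memories[list(FEATURES)]
        )

    def test_raising_one_value_adds_exactly_one_removal(self, small_config):
        ds, _ = generate_cohort(small_config, seed=51)
        # margin: pre-trim at 2*IQR so the single bumped value is the only
        # record near the 3*IQR fence
        prescreened, _ = apply_screening(ds, multiplier=2.0)
        _, r0 = apply_screening(prescreened)
        label = "18-25"
        fence = r0.thresholds[label]
        mem = prescreened.memories
        ages = mem["subject_id"].map(
            prescreened.subjects.set_index("subject_id")["age_years"]
        )
        target = mem.index[
            mem["scored"].astype(bool) & (ages >= 18) & (ages <= 25)
        ][0]
        bumped = prescreened.copy()
        bumped.memories.loc[target, list(FEATURES)] = [int(fence) + 20] + [1] * 7
        _, r1 = apply_screening(bumped)
        assert r1.removed_counts[CONTENT_OUTLIER] == 1
        assert r1.removed_ids[CONTENT_OUTLIER] == [
            bumped.memories.loc[target, "memory_id"]
        ]

    def test_uniform_wins_as_first_removal_reason(self):
        # a majority-uniform pattern subject: their uniform memories carry the
        # memory-level reason, the rest the subject-level reason
        vectors = [[2] * 8, [5] * 8, [1] * 8, [1, 2, 3, 4, 5, 6, 7, 8]]
        filler = {
            f"f{i}": (20, [[1, 2, 1, 3, 1, 2, 4, 1], [2, 1, 3, 1, 2, 1, 1, 4],
                           [0, 1, 2, 1, 0, 3, 1, 2], [3, 1, 0, 2, 1, 1, 2, 0]])
            for i in range(3)
        }
        ds = make_dataset({"s1": (30, vectors), **filler})
        _, report = apply_screening(ds, strata=[(18, 45)])
        assert len(report.removed_ids[UNIFORM_VECTOR]) == 3
        assert len(report.removed_ids[PATTERN_SUBJECT]) == 1

    def test_age_outside_strata_is_config_error(self):
        ds = make_dataset({"s1": (90, [[1, 2, 3, 4, 5, 6, 7, 8]] * 1)})
        with pytest.raises(ConfigError):
            apply_screening(ds, strata=DEFAULT_STRATA)

    def test_removed_memories_stay_dated(self, small_config):
        ds, _ = generate_cohort(small_config, seed=61)
        clean, report = apply_screening(ds)
        assert clean.n_memories == ds.n_memories  # dating rows are never dropped
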