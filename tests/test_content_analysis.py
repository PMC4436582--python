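"""Content summaries, weighting, effect sizes, correlations, subject level."""

import numpy as np
import pandas as pd
import pytest

from cram.core_model import (
    FEATURES,
    InsufficientDataError,
    UndefinedResultError,
    date_memories,
)
from cram.content_analysis import (
    cohens_d,
    compare_event_age_windows,
    feature_contribution,
    feature_correlations,
    feature_profile,
    group_summary,
    group_weighted_mean,
    per_bin_scored_means,
    percent_change,
    subject_level_pipeline,
    weighted_mean_content,
)
from cram.synthetic_cohort import CohortConfig, generate_cohort
from cram.temporal_analysis import TemporalDistribution

from conftest import make_scored_frame


class TestGroupSummary:
    def test_small_example(self):
        s = group_summary([2, 4, 6])
        assert s.mean == 4 and s.median == 4

    def test_cv_is_sd_over_mean(self):
        rng = np.random.default_rng(3)
        totals = rng.gamma(3, 7, size=500)
        s = group_summary(totals)
        assert s.cv == pytest.approx(s.sd / s.mean)

    def test_quantile_convention(self):
        s = group_summary([1, 2, 3, 4, 100])
        assert s.median == 3
        assert s.iqr == 2

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_summary([])


class TestWeightedMean:
    def test_hand_arithmetic(self):
        assert weighted_mean_content([10, 20, 30], [0.2, 0.3, 0.5]) == pytest.approx(23.0)

    def test_uniform_weights_are_simple_average(self):
        assert weighted_mean_content([10, 20, 30], [1 / 3] * 3) == pytest.approx(20.0)

    def test_point_mass_returns_that_bin(self):
        assert weighted_mean_content([10, 20, 30], [0, 1, 0]) == 20.0

    def test_renormalizes_over_scored_bins(self):
        means = [10.0, np.nan, 30.0]
        assert weighted_mean_content(means, [0.25, 0.5, 0.25]) == pytest.approx(20.0)

    def test_no_overlap_rejected(self):
        with pytest.raises(InsufficientDataError):
            weighted_mean_content([np.nan, 10.0], [1.0, 0.0])


class TestFeatureProfile:
    def test_uniform_single_memory(self):
        df = make_scored_frame([[1] * 8])
        prof = feature_profile(df)
        assert prof["share"].tolist() == pytest.approx([0.125] * 8)
        assert prof["presence"].tolist() == pytest.approx([1.0] * 8)

    def test_two_disjoint_memories(self):
        a = [2, 0, 0, 0, 0, 0, 0, 0]
        b = [0, 2, 0, 0, 0, 0, 0, 0]
        prof = feature_profile(make_scored_frame([a, b]))
        assert prof.loc["things", "share"] == 0.5
        assert prof.loc["feelings", "share"] == 0.5
        assert prof.loc["things", "presence"] == 0.5
        assert prof["share"].sum() == pytest.approx(1.0)

    def test_generator_composition_recovered(self):
        cfg = CohortConfig(n_subjects=800)
        ds, _ = generate_cohort(cfg, seed=13)
        dated = date_memories(ds)
        young = dated.loc[dated["age_years"] <= 25]
        prof = feature_profile(young)
        for f in FEATURES:
            assert prof.loc[f, "share"] == pytest.approx(
                cfg.composition["18-25"][f], abs=0.02
            )


class TestFeatureContribution:
    def test_single_feature_difference(self):
        a = {f: 1.0 for f in FEATURES}
        b = dict(a, things=3.0)
        contrib = feature_contribution(a, b)
        assert contrib["things"] == 1.0
        assert contrib.drop("things").sum() == 0.0

    def test_hand_arithmetic(self):
        a = {f: 0.0 for f in FEATURES}
        diffs = dict(zip(FEATURES, (1, 0, 0, 1, 0, 2, 0, 0)))
        contrib = feature_contribution(a, diffs)
        assert contrib["things"] == 0.25
        assert contrib["places"] == 0.25
        assert contrib["episodes"] == 0.5
        assert contrib.sum() == pytest.approx(1.0)

    def test_zero_total_difference_is_undefined(self):
        a = {f: 1.0 for f in FEATURES}
        with pytest.raises(UndefinedResultError):
            feature_contribution(a, a)


class TestCohensD:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected",
        [
            (21.3, 12.1, 24.8, 16.3, 0.24),
            (21.3, 12.1, 25.6, 16.1, 0.30),
            (21.3, 12.1, 24.3, 16.8, 0.20),
        ],
    )
    def test_printed_effect_sizes_under_rms_pooling(self, m1, s1, m2, s2, expected):
        assert round(cohens_d(m1, s1, m2, s2), 2) == expected

    def test_equal_means_give_zero(self):
        assert cohens_d(10, 2, 10, 4) == 0.0

    def test_zero_pooled_sd_with_unequal_means_undefined(self):
        with pytest.raises(UndefinedResultError):
            cohens_d(1, 0, 2, 0)

    def test_n_weighted_pooling(self):
        d = cohens_d(10, 2, 12, 4, pooling="n_weighted", n1=50, n2=50)
        assert d == pytest.approx(2 / np.sqrt((49 * 4 + 49 * 16) / 98))


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref,cmp,expected", [(20, 20, 0.0), (10, 15, 50.0), (21.4, 24.84, 16.07)]
    )
    def test_examples(self, ref, cmp, expected):
        assert percent_change(ref, cmp) == pytest.approx(expected, abs=0.01)

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedResultError):
            percent_change(0, 5)


class TestFeatureCorrelations:
    def test_perfectly_covarying_features(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 10, size=40)
        vectors = [[b, b, 1, 2, 1, 1, 2, 1] for b in base]
        corr, _ = feature_correlations(make_scored_frame(vectors))
        assert corr.loc["things", "feelings"] == pytest.approx(1.0)

    def test_independent_features_near_zero(self):
        rng = np.random.default_rng(2)
        vectors = rng.poisson(3.0, size=(3000, 8))
        corr, _ = feature_correlations(make_scored_frame(vectors))
        off = corr.to_numpy()[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_people_rest_correlation_is_lowest_in_generated_cohort(self):
        ds, _ = generate_cohort(CohortConfig(n_subjects=600), seed=23)
        _, rest = feature_correlations(ds.memories)
        assert rest.idxmin() == "people"


class TestSubjectLevel:
    def test_min_scored_threshold(self, small_config):
        ds, _ = generate_cohort(small_config, seed=5)
        dated = date_memories(ds)
        table = subject_level_pipeline(dated, min_scored=5)
        n_scored = (
            dated.loc[dated["scored"].astype(bool)].groupby("subject_id").size()
        )
        assert set(table["subject_id"]) == set(n_scored.index[n_scored >= 5])

    def test_single_bin_subject_weighted_equals_simple_mean(self):
        vectors = [[1, 2, 1, 3, 0, 1, 2, 1], [2, 1, 0, 4, 1, 0, 1, 2],
                   [1, 1, 1, 2, 2, 1, 0, 3], [0, 2, 2, 1, 1, 3, 1, 0],
                   [3, 0, 1, 1, 2, 2, 1, 1]]
        mem = make_scored_frame(vectors, subject_ids=["s1"] * 5)
        mem["bins"] = [(10,)] * 5
        subjects = pd.DataFrame(
            [{"subject_id": "s1", "age_years": 40, "gender": "female",
              "native_speaker": True, "test_type": "mini", "condition": "internet"}]
        )
        from cram.core_model import Dataset

        dated = date_memories(Dataset(subjects, mem))
        table = subject_level_pipeline(dated, min_scored=5)
        row = table.iloc[0]
        assert row["weighted_mean"] == pytest.approx(row["simple_mean"])
        assert not row["period_eligible"]  # all memories Recent

    def test_subject_level_increase_tracks_memory_level(self):
        ds, _ = generate_cohort(CohortConfig(n_subjects=2500), seed=37)
        dated = date_memories(ds)
        table = subject_level_pipeline(dated, min_scored=5)
        young = table.loc[table["age_years"] <= 45, "weighted_mean"].mean()
        old = table.loc[table["age_years"] >= 46, "weighted_mean"].mean()
        subject_pct = percent_change(young, old)
        from cram.core_model import assign_age_group

        label = assign_age_group(dated, [(18, 45), (46, 78)])
        wm = {
            g: group_weighted_mean(dated.loc[label == g]) for g in ("18-45", "46-78")
        }
        memory_pct = percent_change(wm["18-45"], wm["46-78"])
        assert abs(subject_pct - memory_pct) < 5.0


class TestWindowsAndBins:
    def test_per_bin_means_use_fractional_weights(self):
        mem = make_scored_frame([[8, 0, 0, 0, 0, 0, 0, 0], [0, 4, 0, 0, 0, 0, 0, 0]])
        mem["bins"] = [(1,), (1, 2)]
        mem["total_content"] = [8.0, 4.0]
        means = per_bin_scored_means(mem, n_bins=2)
        # bin 1: weight-1 memory of 8 plus half-weight memory of 4
        assert means[0] == pytest.approx((8 + 0.5 * 4) / 1.5)
        assert means[1] == pytest.approx(4.0)

    def test_bump_window_comparison_runs(self, small_config):
        ds, _ = generate_cohort(small_config, seed=43)
        dated = date_memories(ds)
        result = compare_event_age_windows(dated, (11, 20), (31, 40))
        assert result["d"] >= 0.0
        assert result["window_a"].n > 0
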