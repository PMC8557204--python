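"""Exclusion cascade, redundancy detection/merging, symptom-burden flag."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sympnet import preprocessing, synthetic


def study_flags():
    """Exclusion flags reproducing the cohort's published cascade: 3,363
    baseline participants, of whom 1 intellectual disability, 310 dementia,
    10 refused the medical examination, 182 missing psychiatric assessment."""
    n = 3363
    flags = pd.DataFrame(
        {
            "intellectual_disability": np.zeros(n, dtype=bool),
            "dementia": np.zeros(n, dtype=bool),
            "refused_examination": np.zeros(n, dtype=bool),
            "missing_psychiatric": np.zeros(n, dtype=bool),
        }
    )
    flags.loc[:0, "intellectual_disability"] = True
    flags.loc[1:310, "dementia"] = True
    flags.loc[311:320, "refused_examination"] = True
    flags.loc[321:502, "missing_psychiatric"] = True
    return flags


ORDER = [
    "intellectual_disability",
    "dementia",
    "refused_examination",
    "missing_psychiatric",
]


class TestApplyExclusions:
    def test_reproduces_analytical_sample_size(self):
        mask, report = preprocessing.apply_exclusions(study_flags(), ORDER)
        assert report.n_initial == 3363
        assert [n for _, n in report.steps] == [1, 310, 10, 182]
        assert report.n_final == 2860
        assert mask.sum() == 2860

    def test_no_flags_is_identity(self):
        flags = pd.DataFrame({"a": [False] * 5})
        mask, report = preprocessing.apply_exclusions(flags, ["a"])
        assert report.n_final == 5 and mask.all()

    def test_subject_counted_under_first_criterion_only(self):
        flags = pd.DataFrame({"a": [True, False], "b": [True, True]})
        _, report = preprocessing.apply_exclusions(flags, ["a", "b"])
        assert report.steps == [("a", 1), ("b", 1)]
        assert report.n_final == 0

    def test_n_final_independent_of_order(self):
        flags = study_flags()
        flags.loc[0, "dementia"] = True  # overlap with intellectual disability
        _, r1 = preprocessing.apply_exclusions(flags, ORDER)
        _, r2 = preprocessing.apply_exclusions(flags, ORDER[::-1])
        assert r1.n_final == r2.n_final

    def test_unknown_criterion_raises(self):
        with pytest.raises(KeyError, match="typo"):
            preprocessing.apply_exclusions(study_flags(), ["typo"])

    def test_filters_ratings_when_given(self):
        flags = pd.DataFrame({"a": [False, True, False]})
        ratings = pd.DataFrame({"sympt_01": [0, 1, 2]})
        kept, _ = preprocessing.apply_exclusions(flags, ["a"], ratings)
        assert list(kept["sympt_01"]) == [0, 2]


@pytest.fixture(scope="module")
def planted_cohort():
    spec = synthetic.make_true_network(16, 8, 3, edge_density=0.2, seed=1)
    cohort = synthetic.sample_cohort(spec, n=2000, seed=2)
    return synthetic.inject_redundant_pairs(cohort, 5, latent_corr=0.95, seed=3)


class TestDetectRedundantPairs:
    def test_duplicated_column_flagged(self, small_cohort):
        ratings = small_cohort.ratings.copy()
        ratings["copy"] = ratings[ratings.columns[0]]
        report = preprocessing.detect_redundant_pairs(ratings)
        assert (str(ratings.columns[0]), "copy") in report.flagged

    def test_independent_items_not_flagged(self, rng):
        df = pd.DataFrame(
            rng.integers(0, 7, size=(2000, 6)), columns=[f"i{k}" for k in range(6)]
        )
        report = preprocessing.detect_redundant_pairs(df)
        assert report.flagged == []

    def test_planted_pairs_recovered_exactly(self, planted_cohort):
        report = preprocessing.detect_redundant_pairs(planted_cohort.ratings)
        planted = {tuple(sorted(p)) for p in planted_cohort.truth.redundant_pairs}
        flagged = {tuple(sorted(p)) for p in report.flagged}
        assert flagged == planted

    def test_impossible_threshold_flags_nothing(self, planted_cohort):
        report = preprocessing.detect_redundant_pairs(planted_cohort.ratings, r_min=1.01)
        assert report.flagged == [] and report.merge_map == {}

    def test_merge_map_is_a_partition(self, planted_cohort):
        report = preprocessing.detect_redundant_pairs(planted_cohort.ratings)
        comps = {}
        for item, comp in report.merge_map.items():
            comps.setdefault(comp, []).append(item)
        assert all(len(v) == 2 for v in comps.values())

    def test_constant_item_excluded_with_warning(self, small_cohort):
        ratings = small_cohort.ratings.copy()
        ratings["flat"] = 0
        with pytest.warns(UserWarning, match="flat"):
            report = preprocessing.detect_redundant_pairs(ratings)
        assert not any("flat" in pair for pair in report.flagged)


class TestMergeItems:
    def test_pairwise_average(self):
        df = pd.DataFrame({"a": [2], "b": [4], "c": [1]})
        out = preprocessing.merge_items(df, {"a": "a+b", "b": "a+b"})
        assert out.loc[0, "a+b"] == 3.0
        assert out.loc[0, "c"] == 1

    def test_twentyone_items_with_five_pairs_gives_sixteen(self, planted_cohort):
        report = preprocessing.detect_redundant_pairs(planted_cohort.ratings)
        merged = preprocessing.merge_items(planted_cohort.ratings, report.merge_map)
        assert planted_cohort.ratings.shape[1] == 21
        assert merged.shape[1] == 16

    def test_empty_map_is_identity(self, small_cohort):
        out = preprocessing.merge_items(small_cohort.ratings, {})
        pd.testing.assert_frame_equal(out, small_cohort.ratings)

    def test_missing_member_makes_composite_missing(self):
        df = pd.DataFrame({"a": [2.0, np.nan], "b": [4.0, 3.0]})
        out = preprocessing.merge_items(df, {"a": "ab", "b": "ab"})
        assert out.loc[0, "ab"] == 3.0
        assert np.isnan(out.loc[1, "ab"])

    def test_unknown_item_raises(self):
        df = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(KeyError, match="ghost"):
            preprocessing.merge_items(df, {"ghost": "x", "a": "x"})

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.integers(0, 6), min_size=4, max_size=40))
    def test_merging_preserves_item_range(self, values):
        n = len(values) // 2
        df = pd.DataFrame({"a": values[:n], "b": values[n : 2 * n]})
        out = preprocessing.merge_items(df, {"a": "ab", "b": "ab"})
        assert out["ab"].between(0, 6).all()
        assert out.shape[1] == 1


class TestFlagBurdensome:
    def test_all_zero_not_flagged(self):
        df = pd.DataFrame(np.zeros((3, 10)), columns=[f"i{k}" for k in range(10)])
        flag = preprocessing.flag_burdensome(df, list(df.columns))
        assert not flag.any()

    def test_strict_cutoff_boundary(self):
        df = pd.DataFrame({"a": [6, 7], "b": [0, 0]})
        flag = preprocessing.flag_burdensome(df, ["a", "b"], cutoff=6)
        assert list(flag) == [False, True]

    def test_zero_cutoff_flags_any_positive(self):
        df = pd.DataFrame({"a": [0, 1]})
        flag = preprocessing.flag_burdensome(df, ["a"], cutoff=0)
        assert list(flag) == [False, True]

    def test_missing_item_flags_missing_not_false(self):
        df = pd.DataFrame({"a": [np.nan], "b": [7.0]})
        flag = preprocessing.flag_burdensome(df, ["a", "b"])
        assert flag.isna().iloc[0]
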