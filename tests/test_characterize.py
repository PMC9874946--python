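"""Community profiling, naming, ANOVA, Jaccard concordance, feature-map order."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phenet.characterize import (
    anova_by_feature,
    community_profiles,
    concordance_table,
    feature_map_order,
    jaccard,
    name_community,
    profiles_frame,
)


class TestProfiles:
    def test_means_of_one_community(self):
        f = pd.DataFrame([[0.2, 0.4], [0.4, 0.6]], index=["a", "b"], columns=["x", "y"])
        (p,) = community_profiles(f, {"a": 1, "b": 1})
        assert p.size == 2
        assert p.feature_means["x"] == pytest.approx(0.3)
        assert p.feature_means["y"] == pytest.approx(0.5)

    def test_identical_rows_mean_equals_row(self):
        f = pd.DataFrame([[0.1, 0.9]] * 3, index=list("abc"), columns=["x", "y"])
        (p,) = community_profiles(f, dict.fromkeys("abc", 0))
        assert list(p.feature_means) == pytest.approx([0.1, 0.9])

    def test_means_match_brute_force_and_weighted_mean_conservation(self):
        rng = np.random.default_rng(8)
        f = pd.DataFrame(rng.uniform(0, 1, size=(20, 5)),
                         index=[f"S{i}" for i in range(20)])
        part = {f"S{i}": i % 3 for i in range(20)}
        profiles = community_profiles(f, part)
        total = sum(p.size * p.feature_means for p in profiles)
        pd.testing.assert_series_equal(total, f.sum(axis=0), check_names=False)
        for p in profiles:
            members = [s for s, c in part.items() if c == p.community_id]
            expected = f.loc[members].mean(axis=0)
            assert np.allclose(p.feature_means, expected)

    def test_feature_nodes_excluded_from_bipartite_partition(self):
        f = pd.DataFrame([[0.2, 0.4], [0.4, 0.6]], index=["a", "b"], columns=["x", "y"])
        part = {"a": 0, "b": 0, "x": 0, "y": 1}  # feature nodes share the partition
        (p,) = community_profiles(f, part)
        assert p.size == 2  # subjects only


class TestNaming:
    def test_single_dominant_feature(self):
        means = {"fatigue": 0.9, "pain": 0.3, "gait": 0.2}
        assert name_community(means) == "fatigue"

    def test_runner_up_within_ratio_is_appended(self):
        means = {"hypertonia": 0.8, "weakness": 0.75, "pain": 0.3}
        assert name_community(means) == "hypertonia/weakness"

    def test_runner_up_below_ratio_is_dropped(self):
        means = {"gait": 0.8, "sphincter": 0.5}
        assert name_community(means) == "gait"  # 0.5 < 0.8 * 0.8

    def test_all_zero_means_indeterminate(self):
        assert name_community({"a": 0.0, "b": 0.0}) == "indeterminate"

    def test_exact_tie_breaks_lexicographically(self):
        assert name_community({"pain": 0.6, "gait": 0.6, "x": 0.1}) == "gait/pain"

    def test_scale_invariance(self):
        means = {"a": 0.9, "b": 0.5, "c": 0.2}
        scaled = {k: 7 * v for k, v in means.items()}
        assert name_community(means) == name_community(scaled)


class TestAnova:
    def test_hand_computed_f(self):
        """Groups {1,2,3} and {4,5,6}: SSB = 13.5, SSW = 4, F = 13.5 on (1, 4) df."""
        f = pd.DataFrame({"v": [1, 2, 3, 4, 5, 6]}, index=list("abcdef"))
        part = dict(zip("abcdef", [0, 0, 0, 1, 1, 1]))
        res = anova_by_feature(f, part)
        assert res.loc["v", "F"] == pytest.approx(13.5, abs=1e-12)
        assert res.loc["v", "df_between"] == 1
        assert res.loc["v", "df_within"] == 4
        assert res.loc["v", "p"] == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-12)

    def test_identical_groups_give_f_zero_p_one(self):
        f = pd.DataFrame({"v": [1, 2, 1, 2]}, index=list("abcd"))
        res = anova_by_feature(f, dict(zip("abcd", [0, 0, 1, 1])))
        assert res.loc["v", "F"] == 0.0
        assert res.loc["v", "p"] == 1.0

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        f = pd.DataFrame(rng.normal(size=(30, 4)), index=[f"S{i}" for i in range(30)])
        part = {f"S{i}": i % 3 for i in range(30)}
        res = anova_by_feature(f, part)
        groups = [f.iloc[[i for i in range(30) if i % 3 == g]] for g in range(3)]
        for col in f.columns:
            F, p = stats.f_oneway(*(g[col].values for g in groups))
            assert res.loc[col, "F"] == pytest.approx(F, rel=1e-9)
            assert res.loc[col, "p"] == pytest.approx(p, rel=1e-9)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        f = pd.DataFrame({"v": rng.normal(size=16)}, index=[f"S{i}" for i in range(16)])
        part = {f"S{i}": i % 2 for i in range(16)}
        res = anova_by_feature(f, part)
        a = f["v"][[i % 2 == 0 for i in range(16)]]
        b = f["v"][[i % 2 == 1 for i in range(16)]]
        t, _ = stats.ttest_ind(a, b)
        assert res.loc["v", "F"] == pytest.approx(t**2, abs=1e-9)

    def test_shift_and_scale_invariance_of_f(self):
        rng = np.random.default_rng(3)
        f = pd.DataFrame({"v": rng.normal(size=12)}, index=[f"S{i}" for i in range(12)])
        part = {f"S{i}": i % 2 for i in range(12)}
        base = anova_by_feature(f, part).loc["v", "F"]
        shifted = anova_by_feature(f + 100, part).loc["v", "F"]
        scaled = anova_by_feature(f * 3.7, part).loc["v", "F"]
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_within_nonzero_between_gives_infinite_f(self):
        f = pd.DataFrame({"v": [1, 1, 2, 2]}, index=list("abcd"))
        res = anova_by_feature(f, dict(zip("abcd", [0, 0, 1, 1])))
        assert np.isinf(res.loc["v", "F"])
        assert 0 < res.loc["v", "p"] < 1e-300

    def test_holm_adjustment_optional(self):
        rng = np.random.default_rng(4)
        f = pd.DataFrame(rng.normal(size=(20, 3)), index=[f"S{i}" for i in range(20)])
        part = {f"S{i}": i % 2 for i in range(20)}
        res = anova_by_feature(f, part, holm=True)
        assert (res["p_holm"] >= res["p"] - 1e-15).all()

    def test_degenerate_partitions_rejected(self):
        f = pd.DataFrame({"v": [1, 2, 3]}, index=list("abc"))
        with pytest.raises(ValueError):
            anova_by_feature(f, {"a": 0, "b": 0, "c": 0})
        with pytest.raises(ValueError):
            anova_by_feature(f, {"a": 0, "b": 0, "c": 1})


class TestJaccard:
    @pytest.mark.parametrize(
        "A,B,expected",
        [({1, 2, 3}, {1, 2, 3}, 1.0), ({1, 2}, {3, 4}, 0.0), ({1, 2, 3}, {2, 3, 4}, 0.5)],
    )
    def test_enumerated_values(self, A, B, expected):
        assert jaccard(A, B) == expected

    def test_both_empty_is_hard_error(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_symmetry_range_and_identity(self, A, B):
        if not (A | B):
            return
        j = jaccard(A, B)
        assert j == jaccard(B, A)
        assert 0 <= j <= 1
        assert (j == 1.0) == (A == B)
        assert j == len(A & B) / len(A | B)  # direct set-arithmetic oracle


class TestConcordance:
    def test_identical_partitions_match_perfectly(self):
        p = {f"s{i}": i % 3 for i in range(12)}
        table = concordance_table(p, p)
        assert all(j == 1.0 for _, _, j in table.best_match)
        assert len(table.best_match) == 3

    def test_halved_community_scores_half(self):
        p1 = {f"s{i}": 0 for i in range(8)}
        p2 = {f"s{i}": int(i >= 4) for i in range(8)}
        table = concordance_table(p1, p2)
        assert table.best_match[0][2] == 0.5

    def test_cells_match_direct_set_arithmetic(self):
        rng = np.random.default_rng(9)
        p1 = {f"s{i}": int(rng.integers(0, 4)) for i in range(30)}
        p2 = {f"s{i}": int(rng.integers(0, 3)) for i in range(30)}
        table = concordance_table(p1, p2)
        for r in table.j.index:
            for c in table.j.columns:
                A = {s for s, k in p1.items() if k == r}
                B = {s for s, k in p2.items() if k == c}
                assert table.j.at[r, c] == len(A & B) / len(A | B)

    def test_restricted_to_common_subjects(self):
        p1 = {"a": 0, "b": 0, "only1": 1}
        p2 = {"a": 5, "b": 5, "only2": 6}
        table = concordance_table(p1, p2)
        assert table.j.at[0, 5] == 1.0

    def test_disjoint_subject_sets_rejected(self):
        with pytest.raises(ValueError):
            concordance_table({"a": 0}, {"b": 0})


class TestFeatureMapOrder:
    def test_identical_rows_adjacent(self):
        f = pd.DataFrame(
            [[0, 0, 1], [5, 5, 0], [0, 0, 1.001], [9, 1, 4]],
            index=list("abcd"), columns=["x", "y", "z"], dtype=float,
        )
        rows, _ = feature_map_order(f)
        ia, ic = rows.index("a"), rows.index("c")
        assert abs(ia - ic) == 1

    def test_two_by_two_orders_are_permutations(self):
        f = pd.DataFrame([[1.0, 2.0], [3.0, 0.5]], index=["a", "b"], columns=["x", "y"])
        rows, cols = feature_map_order(f)
        assert sorted(rows) == ["a", "b"] and sorted(cols) == ["x", "y"]

    def test_matches_independent_scipy_reference(self):
        """Cross-check leaf orders against a direct scipy pipeline."""
        from scipy.cluster.hierarchy import leaves_list, linkage
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(10)
        f = pd.DataFrame(rng.uniform(0, 1, size=(6, 4)),
                         index=list("abcdef"), columns=list("wxyz"))
        rows, cols = feature_map_order(f)
        ref_rows = [f.index[i] for i in leaves_list(linkage(pdist(f.values), "ward"))]
        ref_cols = [f.columns[i] for i in
                    leaves_list(linkage(pdist(f.values.T, "correlation"), "ward"))]
        assert rows == ref_rows
        assert cols == ref_cols

    def test_zero_variance_column_pushed_to_edge_without_error(self):
        f = pd.DataFrame(
            {"const": [1.0, 1.0, 1.0], "a": [0, 1, 2], "b": [0, 1.1, 1.9]},
            index=list("abc"),
        )
        rows, cols = feature_map_order(f)
        assert sorted(cols) == ["a", "b", "const"]
        assert "const" in (cols[0], cols[-1])


def test_profiles_frame_tabular_round_trip():
    f = pd.DataFrame([[0.2, 0.4], [0.4, 0.6], [0.9, 0.1]],
                     index=list("abc"), columns=["x", "y"])
    profiles = community_profiles(f, {"a": 1, "b": 1, "c": 2})
    table = profiles_frame(profiles)
    assert list(table["size"]) == [2, 1]
    assert set(table.columns) >= {"size", "name", "x", "y"}
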