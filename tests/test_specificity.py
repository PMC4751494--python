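import io

import numpy as np
import pandas as pd
import pytest

from mirnet.de import DERecord
from mirnet.specificity import (
    SpecificityCriteria,
    abundance_rank_profile,
    apply_alias_map,
    compare_rank_profiles,
    define_specific_set,
    directional_overlap,
    hierarchical_cluster,
    median_center,
    quantile_normalize,
    topk_share,
)
from mirnet.simulate import SimulationConfig, simulate_celltype_panel


def _rec(feature, status, fold=2.5):
    return DERecord(feature, fold, np.log2(fold), 1e-4, 1e-3, status)


class TestQuantileNormalize:
    def test_hand_worked_order_statistic_means(self):
        df = pd.DataFrame({"a": [2, 4, 6], "b": [1, 3, 5]},
                          index=["x", "y", "z"])
        out = quantile_normalize(df)
        assert np.allclose(out["a"], [1.5, 3.5, 5.5])
        assert np.allclose(out["b"], [1.5, 3.5, 5.5])

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        out = quantile_normalize(df)
        assert np.allclose(out, df)

    def test_sorted_columns_identical_and_means_equal(self, rng):
        df = pd.DataFrame(rng.gamma(2.0, 50.0, size=(100, 5)))
        out = quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 5):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)
        assert np.allclose(out.mean(axis=0), out.iloc[:, 0].mean(), atol=1e-9)

    def test_idempotent_on_tie_free_data(self, rng):
        # exact idempotency needs tie-free columns; tied values are
        # span-averaged and re-averaging can drift at the last decimal
        df = pd.DataFrame(rng.gamma(3.0, 20.0, size=(50, 4)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.allclose(once, twice)

    def test_ties_get_mean_of_spanned_quantile_means(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 10.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        # tied entries in 'a' share the mean of the two lowest quantile means
        assert out["a"][0] == out["a"][1]
        ms = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert out["a"][0] == pytest.approx((ms[0] + ms[1]) / 2)

    def test_multi_matrix_join_on_shared_features(self):
        a = pd.DataFrame({"s1": [1.0, 2.0]}, index=["f1", "f2"])
        b = pd.DataFrame({"s2": [3.0, 4.0]}, index=["f2", "f3"])
        out = quantile_normalize([a, b])
        assert list(out.index) == ["f2"]

    def test_no_shared_features_rejected(self):
        a = pd.DataFrame({"s1": [1.0]}, index=["f1"])
        b = pd.DataFrame({"s2": [1.0]}, index=["f2"])
        with pytest.raises(ValueError, match="share"):
            quantile_normalize([a, b])

    def test_alias_map_applied_before_join(self):
        a = pd.DataFrame({"s1": [1.0]}, index=["old-name"])
        mapped = apply_alias_map(a, {"old-name": "new-name"})
        assert list(mapped.index) == ["new-name"]
        with pytest.raises(ValueError, match="collide"):
            apply_alias_map(
                pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"]),
                {"a": "b"},
            )


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        dg = hierarchical_cluster(df, axis="features")
        assert dg.heights[0] == pytest.approx(0.0)

    def test_one_dimensional_average_linkage_arithmetic(self):
        df = pd.DataFrame({"v": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        dg = hierarchical_cluster(df, axis="features")
        assert dg.heights[0] == pytest.approx(1.0)
        assert dg.heights[1] == pytest.approx(9.5)  # (10 + 9) / 2

    def test_median_centering(self):
        df = pd.DataFrame([[1.0, 2.0, 9.0]])
        assert np.allclose(median_center(df), [[-1.0, 0.0, 7.0]])

    def test_no_height_inversions_on_random_data(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        for metric in ("euclidean", "correlation"):
            dg = hierarchical_cluster(df, axis="features", metric=metric)
            assert not dg.has_inversions()

    def test_rows_with_missing_values_excluded(self):
        df = pd.DataFrame(
            [[1.0, 2.0], [np.nan, 3.0], [4.0, 5.0], [6.0, 7.0]]
        )
        dg = hierarchical_cluster(df, axis="features")
        assert len(dg.labels) == 3

    def test_too_few_items_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]])
        with pytest.raises(ValueError):
            hierarchical_cluster(df, axis="features")

    def test_newick_export_parses(self):
        df = pd.DataFrame({"v": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        newick = hierarchical_cluster(df, axis="features").to_newick()
        from Bio import Phylo

        tree = Phylo.read(io.StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c"]

    def test_samples_cluster_by_cell_type_after_quantile_norm(self):
        cfg = SimulationConfig(seed=13, n_celltypes=3, baseline_mean=500.0,
                               platform_shift=0.6)
        panel = simulate_celltype_panel(cfg)
        joined = quantile_normalize(
            [panel.matrices[ct] for ct in panel.cell_types]
        )
        logged = np.log1p(joined)
        dg = hierarchical_cluster(logged, axis="samples")
        clusters = dg.cut(len(panel.cell_types))
        for ct in panel.cell_types:
            cols = [c for c in joined.columns if c.split(":")[-1].startswith(ct)]
            assert len({clusters[c] for c in cols}) == 1, ct


class TestRankProfiles:
    def test_shares_and_ranks(self):
        col = pd.Series([800, 100, 50, 50], index=["a", "b", "c", "d"],
                        name="s")
        prof = abundance_rank_profile(col)
        assert np.allclose(prof.shares, [0.8, 0.1, 0.05, 0.05])
        assert prof.ranks["a"] == 1
        # tie between c and d broken lexicographically
        assert prof.ranks["c"] == 3 and prof.ranks["d"] == 4
        assert prof.shares.sum() == pytest.approx(1.0)

    def test_topk_share_values_and_monotonicity(self):
        col = pd.Series([800, 100, 50, 50], index=list("abcd"), name="s")
        prof = abundance_rank_profile(col)
        assert topk_share(prof, 1) == pytest.approx(0.8)
        assert topk_share(prof, 2) == pytest.approx(0.9)
        assert topk_share(prof, 4) == pytest.approx(1.0)
        shares = [topk_share(prof, k) for k in range(1, 5)]
        assert all(b >= a for a, b in zip(shares, shares[1:]))
        with pytest.raises(ValueError):
            topk_share(prof, 0)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError):
            abundance_rank_profile(pd.Series([0, 0], index=["a", "b"],
                                             name="s"))

    def test_topk_invariant_under_monotone_distortion_of_ranks(self):
        cfg = SimulationConfig(seed=17, platform_shift=0.9)
        panel = simulate_celltype_panel(cfg)
        ct = panel.cell_types[0]
        raw_col = panel.undistorted[ct].iloc[:, 0]
        seen_col = panel.matrices[ct].iloc[:, 0]
        p_raw = abundance_rank_profile(raw_col)
        p_seen = abundance_rank_profile(seen_col)
        assert p_raw.ranks == p_seen.ranks

    def test_compare_identical_profiles_all_similar(self):
        col = pd.Series([5, 3, 1], index=list("abc"), name="s")
        prof = abundance_rank_profile(col)
        rep = compare_rank_profiles(prof, prof, window=0)
        assert (rep["shift"] == 0).all()
        assert rep["similar"].all()

    def test_reversed_ranking_shifts(self):
        a = abundance_rank_profile(
            pd.Series([3, 2, 1], index=list("abc"), name="x"))
        b = abundance_rank_profile(
            pd.Series([1, 2, 3], index=list("abc"), name="y"))
        rep = compare_rank_profiles(a, b, window=0)
        assert rep.loc[["a", "b", "c"], "shift"].tolist() == [2, 0, 2]
        assert rep.loc["b", "similar"]

    def test_disjoint_profiles_rejected(self):
        a = abundance_rank_profile(pd.Series([1], index=["a"], name="x"))
        b = abundance_rank_profile(pd.Series([1], index=["b"], name="y"))
        with pytest.raises(ValueError):
            compare_rank_profiles(a, b)


class TestOverlapAndSpecificSet:
    def test_toy_directional_overlap(self):
        de_a = [_rec("a", "up"), _rec("b", "up"), _rec("d", "down")]
        de_b = [_rec("b", "up"), _rec("c", "up"), _rec("d", "down")]
        rep = directional_overlap(de_a, de_b)
        assert rep.up_overlap == {"b"}
        assert rep.specific_up == {"a"}
        assert rep.down_overlap == {"d"}

    def test_disjoint_de_sets_empty_overlap(self):
        rep = directional_overlap([_rec("a", "up")], [_rec("b", "down")])
        assert not rep.up_overlap and not rep.down_overlap

    def test_opposite_directions_do_not_overlap(self):
        rep = directional_overlap([_rec("a", "up")],
                                  {"a": "Down-regulated"})
        assert not rep.overlapping

    def test_specific_set_removes_overlaps(self):
        de = [_rec("a", "up"), _rec("b", "up"), _rec("c", "down")]
        rep = directional_overlap(de, [_rec("b", "up")])
        assert define_specific_set(de, [rep]) == {"a", "c"}

    def test_empty_overlaps_keep_full_de_set(self):
        de = [_rec("a", "up"), _rec("c", "down")]
        assert define_specific_set(de, []) == {"a", "c"}

    def test_rank_similarity_criterion_excludes_features(self):
        de = [_rec("a", "up"), _rec("b", "up")]
        report = pd.DataFrame(
            {"rank_a": [1, 2], "rank_b": [1, 50], "shift": [0, 48],
             "similar": [True, False]},
            index=pd.Index(["a", "b"], name="feature"),
        )
        got = define_specific_set(
            de, [], [report], SpecificityCriteria(min_similar=1)
        )
        assert got == {"b"}
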