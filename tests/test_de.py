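import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from mirnet.de import (
    DEConfig,
    DifferentialExpression,
    bh_adjust,
    chromosome_distribution,
    classify_status,
    compute_tpm,
    estimate_common_dispersion,
    exact_nb_test,
    normalize_status,
    run_de,
    tmm_factors,
)
from mirnet.matrix import CountMatrix
from mirnet.simulate import SimulationConfig, simulate_counts


class TestTpm:
    def test_direct_formula(self):
        mat = CountMatrix(pd.DataFrame({"s1": [350, 150]}, index=["a", "b"]))
        tpm = compute_tpm(mat, {"s1": 1000})
        assert tpm.data.loc["a", "s1"] == pytest.approx(350000.0)

    def test_single_feature_all_reads_hits_one_million(self):
        mat = CountMatrix(pd.DataFrame({"s1": [1000]}, index=["a"]))
        tpm = compute_tpm(mat, {"s1": 1000})
        assert tpm.data.loc["a", "s1"] == pytest.approx(1e6)

    def test_zero_count_zero_tpm(self):
        mat = CountMatrix(pd.DataFrame({"s1": [0, 10]}, index=["a", "b"]))
        assert compute_tpm(mat, {"s1": 100}).data.loc["a", "s1"] == 0.0

    def test_column_sum_identity(self, toy_counts):
        clean = {"s1": 100, "s2": 100, "s3": 400, "s4": 400}
        tpm = compute_tpm(toy_counts, clean)
        mapped = toy_counts.library_sizes()
        for s in toy_counts.samples:
            assert tpm.data[s].sum() == pytest.approx(
                mapped[s] / clean[s] * 1e6
            )
            assert tpm.data[s].sum() <= 1e6 + 1e-9

    def test_clean_total_below_mapped_rejected(self, toy_counts):
        with pytest.raises(ValueError):
            compute_tpm(toy_counts, {"s1": 1, "s2": 1, "s3": 1, "s4": 1})

    def test_zero_clean_total_rejected(self):
        mat = CountMatrix(pd.DataFrame({"s1": [0]}, index=["a"]))
        with pytest.raises(ValueError):
            compute_tpm(mat, {"s1": 0})


class TestChromosomeDistribution:
    def _mat(self, counts, chroms, groups=None):
        idx = [f"f{i}" for i in range(len(counts))]
        ann = pd.DataFrame({"chromosome": chroms}, index=idx)
        return CountMatrix(
            pd.DataFrame({"s1": counts}, index=idx),
            groups=groups, feature_annotations=ann,
        )

    def test_even_split(self):
        frac, _ = chromosome_distribution(
            self._mat([50, 50], ["chr1", "chr2"])
        )
        assert frac.loc["chr1", "s1"] == pytest.approx(0.5)
        assert frac["s1"].sum() == pytest.approx(1.0)

    def test_single_chromosome_fraction_one(self):
        frac, _ = chromosome_distribution(self._mat([7], ["chr3"]))
        assert frac.loc["chr3", "s1"] == pytest.approx(1.0)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            chromosome_distribution(self._mat([0, 0], ["chr1", "chr2"]))

    def test_group_averages_reported(self, sim_data):
        m, _, _ = sim_data
        frac, avg = chromosome_distribution(m)
        assert avg is not None
        assert list(avg.columns) == m.group_labels()
        assert np.allclose(avg.sum(axis=0), 1.0)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = list(range(1, 101))
        mat = CountMatrix(pd.DataFrame({"a": col, "b": col, "c": col}))
        assert np.allclose(tmm_factors(mat), 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        col = np.arange(1, 101)
        mat = CountMatrix(pd.DataFrame({"a": col, "b": 2 * col}))
        # oracle: every M ratio is 0 after library-size scaling, so the
        # trimmed weighted mean is 0 and both factors are exactly 1
        assert np.allclose(tmm_factors(mat), 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self, sim_data):
        m, _, _ = sim_data
        f = tmm_factors(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_single_sample_rejected(self):
        mat = CountMatrix(pd.DataFrame({"a": [1, 2]}))
        with pytest.raises(ValueError):
            tmm_factors(mat)

    def test_disjoint_support_rejected(self):
        mat = CountMatrix(pd.DataFrame({"a": [5, 5, 0, 0],
                                        "b": [0, 0, 5, 5]}))
        with pytest.raises(ValueError):
            tmm_factors(mat)


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        cfg = SimulationConfig(n_mirna=2000, n_gene=1, dispersion=0.0,
                               frac_de=0.0, seed=31, baseline_mean=100.0)
        m, _, _ = simulate_counts(cfg)
        assert estimate_common_dispersion(m) < 0.02

    def test_nb_dispersion_recovered(self):
        cfg = SimulationConfig(n_mirna=2000, n_gene=1, dispersion=0.1,
                               frac_de=0.0, seed=32, n_per_group=5,
                               baseline_mean=200.0)
        m, _, _ = simulate_counts(cfg)
        assert 0.05 <= estimate_common_dispersion(m) <= 0.2

    def test_constant_counts_clamp_to_zero(self):
        data = pd.DataFrame({"a": [10, 20], "b": [10, 20],
                             "c": [10, 20], "d": [10, 20]},
                            index=["f1", "f2"])
        groups = {"a": "x", "b": "x", "c": "y", "d": "y"}
        assert estimate_common_dispersion(CountMatrix(data, groups)) == 0.0

    def test_no_replicates_rejected(self):
        data = pd.DataFrame({"a": [10], "b": [20]}, index=["f1"])
        mat = CountMatrix(data, {"a": "x", "b": "y"})
        with pytest.raises(ValueError, match="fixed"):
            estimate_common_dispersion(mat)


class TestExactTest:
    def test_poisson_limit_extreme_split_matches_binomial(self):
        # Binomial(10, 1/2): outcomes as unlikely as (0,10) are k=0,10
        p = exact_nb_test(0, 10, 1.0, 1.0, 0.0)
        assert p == pytest.approx(2 / 1024, abs=1e-12)

    def test_balanced_split_is_never_significant(self):
        assert exact_nb_test(7, 7, 1.0, 1.0, 0.1) == pytest.approx(1.0)

    def test_symmetry_under_equal_sizes(self):
        for phi in (0.0, 0.2):
            assert exact_nb_test(3, 12, 5.0, 5.0, phi) == pytest.approx(
                exact_nb_test(12, 3, 5.0, 5.0, phi), abs=1e-12
            )

    def test_zero_total_returns_one(self):
        assert exact_nb_test(0, 0, 1.0, 1.0, 0.1) == 1.0

    def test_phi_zero_agrees_with_exact_binomial_enumeration(self):
        # independent oracle: exact rational binomial tail, p = 1/2
        for t in range(1, 30):
            pmf = [Fraction(math.comb(t, k), 2**t) for k in range(t + 1)]
            for a in range(t + 1):
                expected = float(
                    sum(q for q in pmf if q <= pmf[a])
                )
                got = exact_nb_test(a, t - a, 1.0, 1.0, 0.0)
                assert got == pytest.approx(expected, abs=1e-12), (t, a)

    def test_unequal_sizes_shift_the_null(self):
        # with size_a twice size_b, an even split is already skewed
        p_even = exact_nb_test(10, 10, 2.0, 1.0, 0.0)
        p_prop = exact_nb_test(13, 7, 2.0, 1.0, 0.0)
        assert p_prop > p_even

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test(-1, 5, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            exact_nb_test(1, 5, 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            exact_nb_test(1, 5, 1.0, 1.0, -0.5)


class TestBh:
    def test_hand_worked_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_adjusted_at_least_raw_and_matches_statsmodels(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        from statsmodels.stats.multitest import multipletests

        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adj, sm_adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestClassification:
    def test_huge_fold_tiny_fdr_is_up(self):
        cfg = DEConfig(alpha=0.01)
        assert classify_status(630.71, 7.90e-36, cfg) == "up"

    def test_boundary_half_fold_is_down_inclusive(self):
        cfg = DEConfig(alpha=0.01)
        assert classify_status(0.50, 6.42e-03, cfg) == "down"

    def test_significant_but_small_fold_not_called(self):
        cfg = DEConfig(alpha=0.01)
        assert classify_status(1.5, 1e-9, cfg) == "not_significant"

    def test_status_label_normalization(self):
        assert normalize_status("Up-regulated") == "up"
        assert normalize_status("Not significant") == "not_significant"
        with pytest.raises(ValueError):
            normalize_status("sideways")


class TestRunDe:
    def test_requires_two_groups(self):
        data = pd.DataFrame({"a": [1], "b": [2]}, index=["f"])
        mat = CountMatrix(data, {"a": "x", "b": "x"})
        with pytest.raises(ValueError, match="two groups"):
            run_de(mat)

    def test_fdr_at_least_p_for_every_feature(self, sim_data):
        m, _, _ = sim_data
        for r in run_de(m):
            assert r.fdr >= r.p_value - 1e-15

    def test_status_counts_partition_features(self, sim_data):
        m, _, _ = sim_data
        res = DifferentialExpression(m).fit()
        n_ns = len(res.features_with_status("not_significant"))
        assert res.n_up + res.n_down + n_ns == len(res.records)

    def test_numerator_choice_flips_fold_changes(self, sim_data):
        m, _, _ = sim_data
        a = DifferentialExpression(
            m, DEConfig(numerator="case", denominator="control")
        ).fit()
        b = DifferentialExpression(
            m, DEConfig(numerator="control", denominator="case")
        ).fit()
        fa = a.frame["log2fc"]
        fb = b.frame["log2fc"]
        # pseudocount keeps this from being an exact negation; directionally
        # opposite and strongly anticorrelated is the contract
        assert np.corrcoef(fa, fb)[0, 1] < -0.95

    def test_summary_mentions_contrast_and_counts(self, sim_data):
        m, _, _ = sim_data
        res = DifferentialExpression(m).fit()
        text = res.summary()
        assert "case / control" in text
        assert "up-regulated" in text.lower()
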