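"""Count QC: feature/sample filters, control diagnostics, D statistic,
and median-of-ratios normalization."""

import numpy as np
import pandas as pd
import pytest

from crpod.qc_normalize import (
    control_pca,
    d_statistic,
    filter_features,
    filter_samples,
    normalize,
    pairwise_control_correlations,
    read_layout,
    size_factors,
)


def _frame(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestFilters:
    def test_feature_filter_keeps_rows_with_two_or_more(self):
        counts = _frame([[0, 0], [1, 0], [1, 1], [2, 3]])
        kept, rep = filter_features(counts, min_row_total=2)
        assert list(kept.index) == ["g2", "g3"]
        assert rep.genes_removed == 2
        assert set(rep.removed_genes) == {"g0", "g1"}
        assert rep.genes_in == rep.genes_removed + rep.genes_kept

    def test_feature_filter_zero_threshold_is_identity(self):
        counts = _frame([[0, 0], [5, 1]])
        kept, _ = filter_features(counts, min_row_total=0)
        assert kept.shape == counts.shape

    def test_feature_filter_all_removed_fails(self):
        with pytest.raises(ValueError, match="no features"):
            filter_features(_frame([[0, 1], [1, 0]]), min_row_total=5)

    def test_sample_filter_boundary_keeps_exact_threshold(self):
        counts = _frame([[99_999, 100_000, 250_000]])
        kept, rep = filter_samples(counts, min_col_total=100_000)
        assert list(kept.columns) == ["s1", "s2"]
        assert rep.removed_samples == ["s0"]

    def test_sample_filter_zero_threshold_is_identity(self):
        counts = _frame([[1, 0, 7]])
        kept, _ = filter_samples(counts, min_col_total=0)
        assert kept.shape == counts.shape

    def test_planted_low_count_columns_are_the_ones_dropped(self):
        rng = np.random.default_rng(0)
        counts = _frame(rng.poisson(1000, size=(50, 40)))
        low = ["s3", "s17", "s30"]
        counts[low] = rng.poisson(5, size=(50, 3))
        kept, rep = filter_samples(counts, min_col_total=10_000)
        assert set(rep.removed_samples) == set(low)

    def test_filters_commute_when_independent(self):
        rng = np.random.default_rng(1)
        counts = _frame(rng.poisson(50, size=(30, 8)))
        counts.iloc[0] = 0  # dead feature
        counts["s7"] = 0  # dead sample
        a = filter_samples(filter_features(counts)[0], min_col_total=100)[0]
        b = filter_features(filter_samples(counts, min_col_total=100)[0])[0]
        pd.testing.assert_frame_equal(a, b)


class TestDStatistic:
    def _controls(self, n=24, genes=200, seed=0):
        rng = np.random.default_rng(seed)
        profile = rng.poisson(200, size=genes).astype(float)
        cols = {
            f"c{i}": rng.poisson(profile) for i in range(n)
        }
        return pd.DataFrame(cols)

    def test_shuffled_control_is_unique_exclusion(self):
        counts = self._controls()
        rng = np.random.default_rng(5)
        counts["c7"] = rng.permutation(counts["c7"].to_numpy())
        d, excluded, threshold = d_statistic(counts, list(counts.columns))
        assert excluded == ["c7"]
        assert d["c7"] < threshold

    def test_identical_controls_exclude_nothing(self):
        col = np.arange(1, 51)
        counts = pd.DataFrame({f"c{i}": col for i in range(6)})
        d, excluded, threshold = d_statistic(counts, list(counts.columns))
        assert excluded == []
        assert threshold is None

    def test_zero_variance_control_excluded_with_reason(self):
        counts = self._controls(n=5)
        counts["c4"] = 7  # constant column, correlation undefined
        with pytest.warns(UserWarning, match="zero variance"):
            _, excluded, _ = d_statistic(counts, list(counts.columns))
        assert "c4" in excluded

    def test_exclusion_raises_mean_retained_correlation(self):
        counts = self._controls()
        rng = np.random.default_rng(6)
        counts["c3"] = rng.permutation(counts["c3"].to_numpy())
        ids = list(counts.columns)
        _, excluded, _ = d_statistic(counts, ids)
        kept = [c for c in ids if c not in excluded]

        def mean_corr(cols):
            m = pairwise_control_correlations(counts, cols).to_numpy()
            return (m.sum() - len(cols)) / (len(cols) * (len(cols) - 1))

        assert mean_corr(kept) > mean_corr(ids)

    def test_too_few_controls_rejected(self):
        counts = self._controls(n=3)
        with pytest.raises(ValueError, match="at least 4"):
            d_statistic(counts, list(counts.columns))


class TestPairwiseCorrelations:
    def test_duplicated_columns_give_unit_matrix(self):
        col = np.array([3, 1, 4, 1, 5])
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        corr = pairwise_control_correlations(counts, ["a", "b", "c"])
        assert np.allclose(corr.to_numpy(), 1.0)

    def test_anticorrelated_pair(self):
        # log2(x+0.5) maps these to (1,2,3) and (3,2,1): exactly opposite
        a = np.array([1.5, 3.5, 7.5])
        counts = pd.DataFrame({"a": a, "b": a[::-1]})
        corr = pairwise_control_correlations(counts, ["a", "b"])
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_hand_computation_on_3x3(self):
        # log2 transform inverted so the working values are x=(1,2,4), y=(1,3,2):
        # r = 1 / sqrt((42/9) * 2) = 3 / (2 sqrt(21))
        x = 2.0 ** np.array([1, 2, 4]) - 0.5
        y = 2.0 ** np.array([1, 3, 2]) - 0.5
        counts = pd.DataFrame({"x": x, "y": y})
        corr = pairwise_control_correlations(counts, ["x", "y"])
        assert corr.loc["x", "y"] == pytest.approx(3 / (2 * np.sqrt(21)), abs=1e-12)


class TestControlPCA:
    def _layout(self, samples, vehicle):
        return pd.DataFrame(
            {
                "sample_id": samples,
                "chemical": ["vehicle" if v else "chemX" for v in vehicle],
                "conc_uM": [0.0 if v else 1.0 for v in vehicle],
                "is_vehicle": vehicle,
            }
        )

    def test_identical_controls_have_zero_scores(self):
        col = np.arange(1, 21)
        counts = pd.DataFrame({f"c{i}": col for i in range(4)})
        layout = self._layout(list(counts.columns), [True] * 4)
        scores, evr = control_pca(counts, layout)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-9)

    def test_two_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(100, size=60).astype(float)
        cols = {}
        for i in range(8):
            shift = 4.0 if i >= 4 else 1.0  # second cluster mean-shifted
            cols[f"c{i}"] = rng.poisson(base * shift)
        counts = pd.DataFrame(cols)
        layout = self._layout(list(cols), [True] * 8)
        scores, _ = control_pca(counts, layout)
        signs = np.sign(scores["PC1"].to_numpy())
        assert set(signs[:4]) != set(signs[4:])
        assert len(set(signs[:4])) == 1 and len(set(signs[4:])) == 1

    def test_variance_explained_sums_below_one(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, size=(40, 6)),
                              columns=[f"c{i}" for i in range(6)])
        layout = self._layout(list(counts.columns), [True] * 6)
        _, evr = control_pca(counts, layout)
        assert evr.sum() <= 1.0 + 1e-9

    def test_too_few_controls_warns_and_skips(self):
        counts = pd.DataFrame({"c0": [1, 2], "c1": [2, 3]})
        layout = self._layout(["c0", "c1"], [True, True])
        with pytest.warns(UserWarning, match="fewer than 3"):
            assert control_pca(counts, layout) is None


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = _frame([[10, 10], [20, 20], [30, 30]])
        sf = size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_column_hand_computation(self):
        # column 2 = 2 x column 1: geometric means K*sqrt(2), so ratios are
        # 1/sqrt(2) and sqrt(2) for every gene
        counts = _frame([[10, 20], [20, 40], [40, 80]])
        sf = size_factors(counts)
        assert sf.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_scaling_equivariance(self):
        """Scaling every column by c scales all factors by c and leaves the
        normalized matrix unchanged; scaling one column by c multiplies its
        factor by c relative to the others."""
        rng = np.random.default_rng(4)
        counts = _frame(rng.poisson(100, size=(50, 4)) + 1)
        sf = size_factors(counts)
        # global scaling leaves relative depth (hence the factors) unchanged
        assert np.allclose(size_factors(counts * 3), sf)
        # per-column scaling c_j multiplies factors by c_j up to the global
        # geometric-mean normalization
        c = np.array([1.0, 2.0, 4.0, 8.0])
        sf_scaled = size_factors(counts * c).to_numpy()
        expect = sf.to_numpy() * c
        assert np.allclose(
            sf_scaled / np.exp(np.log(sf_scaled).mean()),
            expect / np.exp(np.log(expect).mean()),
        )
        scaled = counts.copy()
        scaled["s2"] = counts["s2"] * 3
        sf_one = size_factors(scaled)
        assert sf_one["s2"] / sf_one["s0"] == pytest.approx(
            3 * sf["s2"] / sf["s0"], rel=1e-12
        )

    def test_no_common_nonzero_gene_falls_back_to_totals(self):
        counts = _frame([[5, 0], [0, 5]])
        with pytest.warns(UserWarning, match="total-count"):
            sf = size_factors(counts)
        assert np.allclose(sf, 1.0)  # equal totals

    def test_recovers_planted_depth_multipliers(self):
        """Columns drawn from one Poisson profile at known depths: factors
        recover the depths to <5% relative error."""
        rng = np.random.default_rng(8)
        profile = rng.lognormal(np.log(100), 1.0, size=1000)
        depths = np.array([0.5, 1.0, 1.5, 2.0, 3.0])
        counts = _frame(
            np.column_stack([rng.poisson(profile * d) for d in depths])
        )
        sf = size_factors(counts)
        sf = sf / np.exp(np.log(sf).mean())
        target = depths / np.exp(np.log(depths).mean())
        assert np.abs(sf.to_numpy() / target - 1).max() < 0.05


class TestReadLayout:
    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "layout.tsv"
        path.write_text("sample_id\tchemical\tconc_uM\ns1\tchemX\t1.0\n")
        with pytest.raises(ValueError, match="is_vehicle"):
            read_layout(path)

    def test_sample_not_in_layout_rejected(self, tmp_path):
        path = tmp_path / "layout.tsv"
        path.write_text(
            "sample_id\tchemical\tconc_uM\tis_vehicle\ns1\tvehicle\t0\tTrue\n"
        )
        with pytest.raises(ValueError, match="s2"):
            read_layout(path, sample_ids=["s1", "s2"])
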