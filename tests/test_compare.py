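"""Binned profiles, clustering, PCA, overlaps and differential analysis."""

import numpy as np
import pandas as pd
import pytest

import fourcat as fc
from fourcat.compare import (
    bin_profile,
    correlation_cluster,
    differential,
    mean_abs_lfc,
    overlap_sets,
    pca,
    replicate_pearson,
)

SIZES = {"chr1": 5_000_000}


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestBinProfile:
    def test_site_lands_in_start_bin(self):
        prof = bin_profile(_sites([("chr1", 1_500_000, 1_502_000)]), "chr1", SIZES)
        assert prof[1] == 1 and prof.sum() == 1

    def test_empty_sites_all_zero(self):
        prof = bin_profile(_sites([]), "chr1", SIZES)
        assert prof.shape == (5,) and prof.sum() == 0

    def test_counts_conserved_and_trans_ignored(self):
        sites = _sites(
            [("chr1", 0, 2_000), ("chr1", 4_999_000, 5_000_000), ("chr2", 0, 2_000)]
        )
        prof = bin_profile(sites, "chr1", SIZES)
        assert prof.sum() == 2  # only cis sites are counted

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            bin_profile(_sites([("chr1", 5_100_000, 5_102_000)]), "chr1", SIZES)


class TestCorrelationCluster:
    def test_self_correlation_and_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = correlation_cluster({"a": x, "b": x, "c": -x})
        assert res.correlation.loc["a", "b"] == pytest.approx(1.0)
        assert res.correlation.loc["a", "c"] == pytest.approx(-1.0)

    def test_zero_variance_profile_excluded(self):
        res = correlation_cluster(
            {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([2.0, 2.0, 2.0]),
             "c": np.array([3.0, 1.0, 2.0])}
        )
        assert res.excluded == ["b"]
        assert np.isnan(res.correlation.loc["a", "b"])
        assert "b" not in res.leaf_order

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            correlation_cluster({"a": np.zeros(3), "b": np.zeros(4)})

    def test_replicates_pair_together(self, contrast_runs):
        """Dendrogram leaves group replicates within conditions (most seeds)."""
        paired = 0
        for profiles in contrast_runs:
            order = correlation_cluster(profiles).leaf_order
            conds = [s.rsplit("_", 1)[0] for s in order]
            paired += conds in (
                ["quad", "quad", "sol", "sol"], ["sol", "sol", "quad", "quad"]
            )
        assert paired >= 0.9 * len(contrast_runs)


class TestPCA:
    def test_variance_fractions_sum_to_one(self, default_run):
        vp_chrom = default_run.sim_config.viewpoint[0]
        profiles = {
            s: bin_profile(c.significant, vp_chrom, default_run.fmap.chrom_sizes)
            for s, c in default_run.calls.items()
        }
        res = pca(profiles)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_duplicated_samples_coincide(self):
        x = np.array([1.0, 5.0, 2.0, 4.0])
        y = np.array([2.0, 1.0, 6.0, 3.0])
        res = pca({"a1": x, "a2": x.copy(), "b": y})
        np.testing.assert_allclose(
            res.coordinates.loc["a1"], res.coordinates.loc["a2"], atol=1e-9
        )

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca({"a": np.ones(4), "b": np.ones(4)})

    def test_pc1_separates_conditions(self, contrast_runs):
        separated = 0
        for profiles in contrast_runs:
            pc1 = pca(profiles).coordinates["PC1"]
            quad = [pc1[s] for s in pc1.index if s.startswith("quad")]
            sol = [pc1[s] for s in pc1.index if s.startswith("sol")]
            separated += max(quad) < min(sol) or max(sol) < min(quad)
        assert separated >= 0.9 * len(contrast_runs)


class TestOverlapSets:
    def test_worked_example(self):
        ov = overlap_sets({"x": {"A", "B", "C"}, "y": {"B", "C", "D"}})
        assert ov.shared_all == 2
        assert ov.union == 4
        assert ov.shared_fraction == pytest.approx(0.5)

    def test_identical_sets(self):
        ov = overlap_sets({"x": {1, 2}, "y": {1, 2}, "z": {1, 2}})
        assert ov.shared_fraction == 1.0

    def test_partition_counts_sum_to_union(self):
        sets = {"x": {1, 2, 3, 4}, "y": {3, 4, 5}, "z": {4, 5, 6, 7}}
        ov = overlap_sets(sets)
        assert sum(ov.partition_counts.values()) == ov.union

    def test_set_count_limits(self):
        with pytest.raises(ValueError):
            overlap_sets({"a": {1}})
        with pytest.raises(ValueError):
            overlap_sets({n: {1} for n in "abcd"})


def _counts(data, columns):
    return pd.DataFrame(data, columns=columns, dtype=float)


class TestDifferential:
    def test_identical_conditions_give_no_sdis(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(30, size=(40, 2)).astype(float)
        a = _counts(base, ["a1", "a2"])
        b = _counts(base.copy(), ["b1", "b2"])
        res = differential(a, b)
        assert (res.df["log2fc"] == 0).all()
        assert res.df["sdis"].sum() == 0

    def test_spiked_window_flagged(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(20, size=(60, 4)).astype(float)
        base[0] = [0, 0, 100, 100]
        a = _counts(base[:, :2], ["a1", "a2"])
        b = _counts(base[:, 2:], ["b1", "b2"])
        res = differential(a, b)
        assert bool(res.df["sdis"].iloc[0])
        assert res.df["log2fc"].iloc[0] > 1

    def test_label_swap_negates_lfc_and_keeps_pvalues(self):
        rng = np.random.default_rng(2)
        a = _counts(rng.poisson(25, size=(50, 2)), ["a1", "a2"])
        b = _counts(rng.poisson(35, size=(50, 2)), ["b1", "b2"])
        fwd = differential(a, b)
        rev = differential(b, a)
        np.testing.assert_allclose(fwd.df["log2fc"], -rev.df["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd.df["pvalue"], rev.df["pvalue"], atol=1e-12)

    def test_bh_monotone_and_padj_at_least_p(self):
        rng = np.random.default_rng(3)
        a = _counts(rng.poisson(25, size=(80, 2)), ["a1", "a2"])
        b = _counts(rng.poisson(28, size=(80, 2)), ["b1", "b2"])
        df = differential(a, b).df
        assert (df["padj"] >= df["pvalue"] - 1e-12).all()
        assert df.sort_values("pvalue")["padj"].is_monotonic_increasing

    def test_replicate_and_alignment_requirements(self):
        a = _counts([[1], [2]], ["a1"])
        b = _counts([[1, 2], [2, 3]], ["b1", "b2"])
        with pytest.raises(ValueError):
            differential(a, b)
        a2 = _counts([[1, 2], [2, 3]], ["a1", "a2"])
        b2 = b.copy()
        b2.index = [5, 6]
        with pytest.raises(ValueError):
            differential(a2, b2)

    def test_permuted_labels_control_sdis_rate(self):
        """Swapping one replicate across conditions should kill real signal."""
        rates = []
        for seed in range(8):
            rng = np.random.default_rng(500 + seed)
            counts = rng.poisson(30, size=(60, 4)).astype(float)
            a = _counts(counts[:, [0, 2]], ["a1", "a2"])  # mixed labels
            b = _counts(counts[:, [1, 3]], ["b1", "b2"])
            rates.append(differential(a, b).df["sdis"].mean())
        assert np.mean(rates) <= 0.05


class TestMeanAbsLFC:
    def _result(self, lfcs, sdis):
        df = pd.DataFrame(
            {"log2fc": lfcs, "pvalue": 0.5, "padj": 0.5, "sdis": sdis}
        )
        return fc.DifferentialResult(df=df, size_factors=pd.Series(dtype=float),
                                     lfc_min=1.0, alpha=0.05)

    def test_worked_example(self):
        res = self._result([1.0, -3.0], [True, True])
        assert mean_abs_lfc(res) == pytest.approx(2.0)

    def test_all_zero(self):
        res = self._result([0.0, 0.0], [False, False])
        assert mean_abs_lfc(res, sdis_only=False) == 0.0

    def test_empty_selection_rejected(self):
        res = self._result([1.0], [False])
        with pytest.raises(ValueError):
            mean_abs_lfc(res)

    def test_sdis_mean_at_least_overall_mean(self, default_run):
        res = default_run.differential
        assert mean_abs_lfc(res, sdis_only=True) >= mean_abs_lfc(res, sdis_only=False)


def test_replicate_pearson_nan_for_constant_profile():
    assert np.isnan(replicate_pearson(np.ones(5), np.arange(5.0)))
    assert replicate_pearson(np.arange(5.0), np.arange(5.0)) == pytest.approx(1.0)
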