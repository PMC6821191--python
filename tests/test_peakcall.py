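"""Clustering, maxima refinement, replicate merging, counting, normalization."""

import numpy as np
import pandas as pd
import pytest

from ficcseq.peakcall import (
    RefineParams,
    annotate_peaks,
    cluster_sites,
    correlate,
    count_clusters,
    merge_replicates,
    normalize_counts,
    overlap_peaks,
    refine_maxima,
    size_factors_median_of_ratios,
)
from ficcseq.simdata import Gene


def _sites(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "strand", "pos", "count"])


class TestClusterSites:
    def test_nearby_sites_form_one_cluster(self):
        out = cluster_sites(_sites([("s", "c", "+", 100, 5), ("s", "c", "+", 104, 3)]), 10)
        assert out["cluster_id"].nunique() == 1

    def test_distant_sites_split(self):
        out = cluster_sites(_sites([("s", "c", "+", 100, 5), ("s", "c", "+", 150, 3)]), 10)
        assert out["cluster_id"].nunique() == 2

    def test_strands_never_mix(self):
        out = cluster_sites(_sites([("s", "c", "+", 100, 5), ("s", "c", "-", 101, 3)]), 10)
        assert out["cluster_id"].nunique() == 2

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        rows = [("s", "c", "+", int(p), 1) for p in np.sort(rng.choice(500, 60, replace=False))]
        out = cluster_sites(_sites(rows), 7)
        assert len(out) == 60
        assert out["cluster_id"].notna().all()


class TestRefineMaxima:
    def test_single_peak(self):
        assert refine_maxima([0, 1, 2], [0, 5, 0], 0.3, 2) == [1]

    def test_major_plus_subpeak(self):
        pos = np.arange(7)
        cnt = [0, 100, 0, 0, 0, 40, 0]
        assert refine_maxima(pos, cnt, 0.3, 2) == [1, 5]

    def test_plateau_reports_leftmost(self):
        assert refine_maxima([0, 1, 2, 3], [0, 7, 7, 0], 0.3, 2) == [1]

    def test_rel_threshold_drops_small_maxima(self):
        pos = np.arange(7)
        cnt = [0, 100, 0, 0, 0, 20, 0]
        assert refine_maxima(pos, cnt, 0.3, 2) == [1]

    def test_min_dist_suppresses_close_secondary(self):
        assert refine_maxima([0, 1, 2], [80, 0, 100], 0.3, 5) == [2]

    def test_invariant_under_uniform_scaling(self):
        rng = np.random.default_rng(8)
        cnt = rng.integers(0, 50, size=30)
        pos = np.arange(30)
        base = refine_maxima(pos, cnt, 0.3, 2)
        assert refine_maxima(pos, cnt * 17, 0.3, 2) == base


class TestMergeReplicates:
    def _peaks(self, rows):
        return pd.DataFrame(rows, columns=["sample", "chrom", "strand", "pos", "count"])

    def test_identical_positions_unify(self):
        out = merge_replicates(
            self._peaks([("A", "c", "+", 999, 10), ("B", "c", "+", 999, 12)]), 3
        )
        assert len(out) == 1
        assert out.iloc[0]["pos"] == 999
        assert out.iloc[0]["replicates"] == "A,B"

    def test_nearby_positions_use_summed_count_rule(self):
        out = merge_replicates(
            self._peaks(
                [("A", "c", "+", 999, 10), ("B", "c", "+", 1001, 12), ("A", "c", "+", 1001, 3)]
            ),
            3,
        )
        assert len(out) == 1
        assert out.iloc[0]["pos"] == 1001  # 12+3 > 10

    def test_zero_tolerance_concatenates_disjoint_sets(self):
        out = merge_replicates(
            self._peaks([("A", "c", "+", 10, 1), ("B", "c", "+", 30, 1)]), 0
        )
        assert len(out) == 2

    def test_commutative_in_replicate_order(self):
        rows = [("A", "c", "+", 10, 5), ("B", "c", "+", 12, 7), ("B", "c", "-", 40, 2)]
        a = merge_replicates(self._peaks(rows), 3)
        b = merge_replicates(self._peaks(rows[::-1]), 3)
        pd.testing.assert_frame_equal(a, b)


class TestCountClusters:
    def _final(self):
        return pd.DataFrame(
            [dict(final_id="p1", chrom="c", strand="+", start=100, end=105, pos=102,
                  replicates="A", total_count=1)]
        )

    def _cdna(self, sample, strand, start, end):
        return dict(sample=sample, chrom="c", strand=strand, five_prime_pos=start,
                    umi="AA", support=1, start=start, end=end)

    def test_any_overlap_counts(self):
        cdnas = pd.DataFrame([self._cdna("A", "+", 95, 130)])
        assert count_clusters(self._final(), cdnas).loc["p1", "A"] == 1

    def test_opposite_strand_not_counted(self):
        cdnas = pd.DataFrame([self._cdna("A", "-", 95, 130)])
        assert count_clusters(self._final(), cdnas).loc["p1", "A"] == 0

    def test_non_overlapping_not_counted(self):
        cdnas = pd.DataFrame([self._cdna("A", "+", 105, 130)])
        assert count_clusters(self._final(), cdnas).loc["p1", "A"] == 0


class TestNormalize:
    def _random_matrix(self, seed=0, shape=(50, 4)):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.integers(1, 200, size=shape),
            index=[f"cl{i}" for i in range(shape[0])],
            columns=[f"s{j}" for j in range(shape[1])],
        )

    def test_identical_samples_give_unit_factors(self):
        m = self._random_matrix()
        m["s1"] = m["s0"]
        factors, _ = normalize_counts(m[["s0", "s1"]], min_total=0)
        assert np.allclose(factors, [1, 1])

    def test_scale_equivariance(self):
        m = self._random_matrix()
        doubled = m.copy()
        doubled["s1"] = 2 * m["s0"]
        base = m.copy()
        base["s1"] = m["s0"]
        f, norm = normalize_counts(doubled[["s0", "s1"]], min_total=0)
        assert np.isclose(f["s1"] / f["s0"], 2.0)
        assert np.allclose(norm["s0"], norm["s1"])

    def test_median_of_ratios_matches_independent_reimplementation(self):
        """Estimator agrees to 1e-12 with a directly coded reference."""
        m = self._random_matrix(seed=7)
        factors = size_factors_median_of_ratios(m)
        # independent oracle: per-cluster geometric mean, median of ratios
        arr = m.to_numpy(dtype=float)
        keep = (arr > 0).all(axis=1)
        gm = np.exp(np.log(arr[keep]).mean(axis=1))
        expected = [np.median(arr[keep, j] / gm) for j in range(arr.shape[1])]
        assert np.allclose(factors.to_numpy(), expected, atol=1e-12, rtol=0)

    def test_multiplying_one_sample_scales_its_factor_relative_to_others(self):
        """Scaling one sample's counts by c multiplies its size factor by c
        relative to every other sample (the geometric-mean reference itself
        absorbs a c^(1/m) shift, so only factor ratios are identified)."""
        m = self._random_matrix(seed=2)
        scaled = m.copy()
        scaled["s2"] = m["s2"] * 5
        f0, _ = normalize_counts(m, min_total=0)
        f1, _ = normalize_counts(scaled, min_total=0)
        for other in ("s0", "s1", "s3"):
            assert np.isclose((f1["s2"] / f1[other]) / (f0["s2"] / f0[other]), 5.0)

    def test_min_total_prefilter(self):
        m = pd.DataFrame({"a": [1, 100], "b": [2, 120]}, index=["lo", "hi"])
        _, norm = normalize_counts(m, min_total=10)
        assert list(norm.index) == ["hi"]

    def test_total_count_mode_follows_library_sizes(self):
        m = self._random_matrix(seed=3)
        f, _ = normalize_counts(m, min_total=0, method="total_count")
        totals = m.sum(axis=0)
        assert np.allclose(f, totals / totals.mean())

    def test_all_zero_containing_matrix_falls_back_with_warning(self):
        m = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.warns(UserWarning):
            f, _ = normalize_counts(m, min_total=0)
        assert (f > 0).all()


class TestCorrelate:
    def test_self_and_scaled_column(self):
        m = pd.DataFrame({"a": [1, 5, 20, 7], "b": [2, 10, 40, 14]})
        c = correlate(m)
        assert np.isclose(c.loc["a", "a"], 1.0)
        # log-scale: r(x, 2x) is affine-high but not exactly 1
        assert c.loc["a", "b"] > 0.999

    def test_zero_variance_column_reported_missing(self):
        m = pd.DataFrame({"a": [1, 5, 20], "b": [3, 3, 3]})
        c = correlate(m)
        assert np.isnan(c.loc["a", "b"])
        assert np.isnan(c.loc["b", "b"])


class TestOverlapPeaks:
    def _peaks(self, positions, count=10):
        return pd.DataFrame(
            [dict(chrom="c", strand="+", pos=p, count=count) for p in positions]
        )

    def test_identical_sets_fully_shared(self):
        pos = [10, 50, 90]
        venn, frac = overlap_peaks(
            {"A": self._peaks(pos), "B": self._peaks(pos)}, reference="A"
        )
        assert venn == {frozenset({"A", "B"}): 3}
        assert frac == 1.0

    def test_disjoint_sets(self):
        venn, frac = overlap_peaks(
            {"A": self._peaks([10, 50]), "B": self._peaks([200, 300])}, reference="A"
        )
        assert venn == {frozenset({"A"}): 2, frozenset({"B"}): 2}
        assert frac == 0.0

    def test_reference_fraction_arithmetic(self):
        a = list(range(0, 100, 10))  # 10 peaks
        b = a[:9] + [500]
        _, frac = overlap_peaks(
            {"A": self._peaks(a), "B": self._peaks(b)}, merge_tol=3, reference="A"
        )
        assert np.isclose(frac, 0.9)

    def test_min_count_filter(self):
        venn, _ = overlap_peaks(
            {"A": self._peaks([10], count=4), "B": self._peaks([10], count=6)},
            min_count=5,
        )
        assert venn == {frozenset({"B"}): 1}


class TestAnnotatePeaks:
    def _genes(self):
        return [
            Gene("t1", "c", 0, 100, "+", "tRNA"),
            Gene("o1", "c", 200, 300, "+", "other"),
        ]

    def _final(self, positions_counts):
        return pd.DataFrame(
            [
                dict(final_id=f"p{i}", chrom="c", strand="+", start=p, end=p + 1,
                     pos=p, replicates="A", total_count=n)
                for i, (p, n) in enumerate(positions_counts)
            ]
        )

    def test_all_trna(self):
        out = annotate_peaks(self._final([(10, 5), (50, 5)]), self._genes())
        assert out.set_index("gene_class").loc["tRNA", "peak_fraction"] == 1.0

    def test_mixed_classes_and_count_weighting(self):
        out = annotate_peaks(self._final([(10, 30), (250, 10)]), self._genes()).set_index("gene_class")
        assert out.loc["tRNA", "peak_fraction"] == 0.5
        assert np.isclose(out.loc["tRNA", "count_fraction"], 0.75)

    def test_empty_peak_list(self):
        out = annotate_peaks(self._final([]).iloc[0:0], self._genes())
        assert out.empty
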