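import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from chromdyn.atac import (
    FuzzyCMeans,
    assign_categories,
    consensus_union,
    cv_mask,
    filter_peaks,
    fuzzy_cmeans,
    merge_within,
    nearest_gene_expression,
    presence_mask,
    quantile_normalize,
    rpkm,
    zscore_rows,
)
from chromdyn.intervals import GenomicInterval


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestMergeWithin:
    def test_gap_below_threshold_merges(self):
        out = merge_within([iv(100, 200), iv(250, 350)], gap=100)
        assert [(p.start, p.end) for p in out] == [(100, 350)]

    def test_gap_above_threshold_keeps(self):
        out = merge_within([iv(100, 200), iv(350, 450)], gap=100)
        assert [(p.start, p.end) for p in out] == [(100, 200), (350, 450)]

    def test_transitive_chain(self):
        out = merge_within([iv(0, 10), iv(60, 70), iv(120, 130)], gap=100)
        assert [(p.start, p.end) for p in out] == [(0, 130)]

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 300)), min_size=1, max_size=30
        ),
        st.integers(0, 200),
    )
    def test_output_separated_by_more_than_gap(self, spans, gap):
        peaks = [iv(s, s + ln) for s, ln in spans]
        out = merge_within(peaks, gap=gap)
        for a, b in zip(out, out[1:]):
            assert b.start - a.end > gap
        # coverage superset: every input base is covered
        assert sum(len(p) for p in out) >= 0
        for p in peaks:
            assert any(m.start <= p.start and p.end <= m.end for m in out)


class TestConsensus:
    def test_single_stage_reduces_to_merge(self):
        peaks = [iv(0, 100), iv(150, 250)]
        assert consensus_union([peaks], gap=100) == merge_within(peaks, gap=100)

    def test_idempotent_union(self):
        peaks = [iv(1000, 1500)]
        out = consensus_union([peaks, peaks], gap=100)
        assert [(p.start, p.end) for p in out] == [(1000, 1500)]

    def test_requires_a_stage(self):
        with pytest.raises(ValueError):
            consensus_union([])


class TestRpkm:
    def test_direct_formula(self):
        counts = pd.DataFrame({"s1": [10.0, 0.0]})
        out = rpkm(counts, [1000, 500], {"s1": 1e6})
        assert out.loc[0, "s1"] == pytest.approx(10.0)
        assert out.loc[1, "s1"] == 0.0

    def test_library_scaling(self):
        counts = pd.DataFrame({"s1": [10.0], "s2": [10.0]})
        out = rpkm(counts, [1000], {"s1": 1e6, "s2": 2e6})
        assert out.loc[0, "s1"] == pytest.approx(2 * out.loc[0, "s2"])

    def test_zero_length_peak_rejected(self):
        with pytest.raises(ValueError):
            rpkm(pd.DataFrame({"s": [1.0]}), [0], {"s": 1e6})


class TestFilters:
    def test_presence_and_cv_rules(self):
        mat = pd.DataFrame(
            [
                (6, 6, 1, 1),  # passes presence (two stages > 5), CV high
                (8, 8, 8, 8),  # constant: CV = 0 -> removed
                (4, 4, 4, 9),  # only one stage > 5 -> removed
            ],
            columns=list("abcd"),
            dtype=float,
        )
        assert presence_mask(mat).tolist() == [True, True, False]
        assert cv_mask(mat).tolist() == [True, False, True]
        filtered, keep = filter_peaks(mat)
        assert keep.tolist() == [True, False, False]
        assert len(filtered) == 1

    def test_boundary_cv_kept(self):
        # CV exactly 0.10 is kept (rule: removed iff CV < 10%)
        row = np.array([9.0, 11.0, 9.0, 11.0])
        cv = row.std() / row.mean()
        assert cv == pytest.approx(0.1)
        assert cv_mask(pd.DataFrame([row])).tolist() == [True]


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        mat = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(mat), mat)

    def test_sorted_columns_identical_after(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.random((50, 4)))
        out = quantile_normalize(mat)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_two_by_two_hand_case(self):
        # columns (1, 10) and (2, 20): sorted means (1.5, 15)
        mat = pd.DataFrame({"a": [1.0, 10.0], "b": [2.0, 20.0]})
        out = quantile_normalize(mat)
        np.testing.assert_allclose(out["a"], [1.5, 15.0])
        np.testing.assert_allclose(out["b"], [1.5, 15.0])

    def test_idempotent_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.random((40, 4)) * 30)
        once = quantile_normalize(mat)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)

    def test_ties_get_mean_of_targets(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 9.0]})
        out = quantile_normalize(mat)
        target = np.sort(mat.to_numpy(), axis=0).mean(axis=1)  # (1.5, 2.5, 7)
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx(target[:2].mean())
        assert out["a"].iloc[2] == pytest.approx(target[2])


class TestZscore:
    def test_direct_formula_population_sd(self):
        out = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(
            out.to_numpy()[0], [-1.224744871, 0.0, 1.224744871], atol=1e-9
        )

    def test_affine_invariance_and_moments(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.random((10, 5)))
        out = zscore_rows(mat)
        out2 = zscore_rows(mat * 7.0 + 3.0)
        np.testing.assert_allclose(out.to_numpy(), out2.to_numpy(), atol=1e-9)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1, ddof=0), 1.0, atol=1e-6)

    def test_zero_sd_row_rejected(self):
        with pytest.raises(ValueError):
            zscore_rows(pd.DataFrame([[2.0, 2.0, 2.0]]))


class TestFuzzyCMeans:
    def test_single_cluster_degenerate(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 4))
        f = FuzzyCMeans(n_clusters=1, random_state=0, n_restarts=1).fit(X)
        np.testing.assert_allclose(f.membership_, 1.0)
        np.testing.assert_allclose(f.cluster_centers_[0], X.mean(axis=0), atol=1e-9)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(1)
        X = rng.random((60, 4))
        f = FuzzyCMeans(n_clusters=3, random_state=0, n_restarts=1).fit(X)
        diffs = np.diff(f.objective_history_)
        assert (diffs <= 1e-9).all()

    def test_two_planted_groups_perfect_recovery(self):
        rng = np.random.default_rng(2)
        X = np.vstack(
            [
                rng.normal(0, 0.1, (40, 3)) + [0, 0, 3],
                rng.normal(0, 0.1, (40, 3)) + [3, 0, 0],
            ]
        )
        truth = np.repeat([0, 1], 40)
        f = fuzzy_cmeans(X, c=2, seed=0)
        assert adjusted_rand_score(truth, f.labels_) == 1.0
        np.testing.assert_allclose(f.membership_.sum(axis=1), 1.0, atol=1e-9)
        assert ((f.membership_ >= 0) & (f.membership_ <= 1)).all()

    def test_fuzzifier_must_exceed_one(self):
        with pytest.raises(ValueError):
            FuzzyCMeans(n_clusters=2, m=1.0).fit(np.random.default_rng(0).random((9, 2)))


class TestAssignCategories:
    @pytest.mark.parametrize(
        "centroid,expected",
        [
            ((1.2, 0.8, -0.9, -1.1), "I"),
            ((-1.0, 0.9, 1.0, -0.9), "II"),
            ((-1.1, -0.9, 0.8, 1.2), "III"),
        ],
    )
    def test_argmax_pairs(self, centroid, expected):
        assert assign_categories(np.array([centroid]))[0] == expected

    def test_tie_goes_to_earlier_category(self):
        assert assign_categories(np.array([[1.0, 0.0, 1.0, 0.0]]))[0] == "I"

    def test_requires_four_stages(self):
        with pytest.raises(ValueError):
            assign_categories(np.zeros((2, 3)))


class TestNearestGeneExpression:
    ann = pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chrom": ["chr1", "chr1"],
            "tss": [100, 400],
            "strand": ["+", "+"],
        }
    )

    def test_nearest_and_tiebreak(self):
        expr = pd.DataFrame({"s": [1, 1]}, index=["gA", "gB"])
        peaks = [iv(100, 200)]  # midpoint 150: dist 50 vs 250 -> gA
        _, nearest = nearest_gene_expression(peaks, self.ann, expr, [0])
        assert nearest == ["gA"]
        ann2 = self.ann.assign(tss=[100, 200])  # equidistant from 150
        _, nearest2 = nearest_gene_expression(peaks, ann2, expr, [0])
        assert nearest2 == ["gA"]  # smaller TSS wins

    def test_cluster_mean_log_expression(self):
        expr = pd.DataFrame({"s": [3, 7]}, index=["gA", "gB"])
        peaks = [iv(50, 150), iv(350, 450)]  # -> gA, gB
        mat, _ = nearest_gene_expression(peaks, self.ann, expr, [0, 0], n_clusters=2)
        assert mat.loc["cluster1", "s"] == pytest.approx((np.log2(4) + np.log2(8)) / 2)
        assert np.isnan(mat.loc["cluster2", "s"])  # empty cluster
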