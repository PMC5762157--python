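import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import squareform

import songeval as se
from songeval.similarity import DistanceMatrix, UNCLASSIFIED

from conftest import dtw_brute_force


def _random_summary_frame(rng, n):
    cols = pd.Index([f"c{i}" for i in range(101)])
    return pd.DataFrame(rng.standard_normal((n, 101)), columns=cols,
                        index=[f"s{i}" for i in range(n)])


class TestSummaryEuclidean:
    def test_identical_vectors_distance_zero(self):
        df = _random_summary_frame(np.random.default_rng(0), 3)
        df.iloc[1] = df.iloc[0]
        d = se.summary_euclidean(df)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_matches_hand_computed_norms_unstandardized(self):
        rng = np.random.default_rng(1)
        df = _random_summary_frame(rng, 5)
        d = se.summary_euclidean(df, standardize=False)
        x = df.to_numpy()
        for i in range(5):
            for j in range(5):
                assert d.values[i, j] == pytest.approx(
                    np.linalg.norm(x[i] - x[j])
                )

    def test_dimension_mismatch_rejected(self):
        df = pd.DataFrame(np.zeros((3, 99)))
        with pytest.raises(ValueError, match="101"):
            se.summary_euclidean(df)


class TestDTW:
    def test_self_distance_zero_any_penalty(self, repertoire):
        tr, _ = se.render_rendition(repertoire[0],
                                    se.DistortionSpec(delta=0.3, seed=1))
        for pen in (0.0, 1.0, 100.0):
            assert se.dtw_distance(tr, tr, pen) == pytest.approx(0.0)

    def test_small_tracks_match_brute_force_enumeration(self):
        a = np.array([0.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 1.0, 0.0])
        assert se.dtw_distance(a, b, 0.0) == pytest.approx(
            dtw_brute_force(a, b, 0.0)
        )
        rng = np.random.default_rng(2)
        for _ in range(50):
            n, m = rng.integers(1, 7, size=2)
            x = rng.standard_normal((n, 2))
            y = rng.standard_normal((m, 2))
            pen = float(rng.uniform(0, 2))
            assert se.dtw_distance(x, y, pen) == pytest.approx(
                dtw_brute_force(x, y, pen)
            )

    def test_infinite_penalty_reduces_to_framewise_cost(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((5, 2))
        y = rng.standard_normal((5, 2))
        framewise = np.linalg.norm(x - y, axis=1).sum()
        assert se.dtw_distance(x, y, 1e12) == pytest.approx(framewise)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((4, 3)), rng.standard_normal((6, 3))
        assert se.dtw_distance(x, y, 0.7) == pytest.approx(
            se.dtw_distance(y, x, 0.7)
        )

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            se.dtw_distance(np.empty((0, 2)), np.ones((3, 2)), 0.5)


def _dm(values, channel="summary_euclidean"):
    n = values.shape[0]
    return DistanceMatrix(values, [f"s{i}" for i in range(n)], channel)


class TestPercentileNormalize:
    def test_distinct_distances_map_to_rank_grid(self):
        v = squareform(np.array([1.0, 2.0, 3.0]))
        p = se.percentile_normalize(_dm(v))
        got = sorted(squareform(p.values, checks=False))
        assert got == pytest.approx([0.5 / 3, 1.5 / 3, 2.5 / 3])

    def test_ties_get_mid_rank(self):
        v = squareform(np.array([1.0, 1.0, 3.0]))
        p = se.percentile_normalize(_dm(v))
        cond = squareform(p.values, checks=False)
        assert cond[0] == cond[1] == pytest.approx(1.0 / 3)

    def test_all_tied_collapse_to_half(self):
        v = squareform(np.array([2.0, 2.0, 2.0]))
        p = se.percentile_normalize(_dm(v))
        assert np.allclose(squareform(p.values, checks=False), 0.5)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_rank_transform_idempotent_in_ordering(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        v = squareform(rng.uniform(0.1, 5.0, n * (n - 1) // 2))
        p1 = se.percentile_normalize(_dm(v))
        p2 = se.percentile_normalize(p1)
        c1 = squareform(p1.values, checks=False)
        c2 = squareform(p2.values, checks=False)
        assert np.array_equal(np.argsort(c1, kind="stable"),
                              np.argsort(c2, kind="stable"))


class TestCombineAndIndex:
    def test_geometric_mean_identity_and_arithmetic(self):
        v = squareform(np.array([0.25, 0.5, 0.75]))
        p = _dm(v, "percentile")
        assert np.allclose(se.combine(p, p).values, p.values)
        q = _dm(squareform(np.array([1.0, 0.5, 0.75])), "percentile")
        comb = se.combine(p, q)
        assert comb.values[0, 1] == pytest.approx(0.5)  # sqrt(0.25 * 1.0)
        assert np.all(comb.values <= (p.values + q.values) / 2 + 1e-12)

    def test_id_mismatch_rejected(self):
        p = _dm(np.zeros((3, 3)), "percentile")
        q = DistanceMatrix(np.zeros((3, 3)), ["a", "b", "c"], "percentile")
        with pytest.raises(ValueError, match="id mismatch"):
            se.combine(p, q)

    def test_identical_rows_give_zero(self):
        v = np.array(
            [[0.0, 1.0, 2.0, 3.0],
             [1.0, 0.0, 2.0, 3.0],
             [2.0, 2.0, 0.0, 1.0],
             [3.0, 3.0, 1.0, 0.0]]
        )
        v[1] = v[0]
        v[:, 1] = v[:, 0]
        d = se.dissimilarity_index(_dm(v, "combined"))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_rows_give_two(self):
        # rows 0 and 1 satisfy row1 = 1 - row0 exactly (correlation -1)
        v = np.array(
            [[0.0, 1.0, 0.25, 0.75],
             [1.0, 0.0, 0.75, 0.25],
             [0.25, 0.75, 0.0, 0.5],
             [0.75, 0.25, 0.5, 0.0]]
        )
        d = se.dissimilarity_index(_dm(v, "combined"))
        assert d.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_hand_computed_row_correlations(self):
        rng = np.random.default_rng(5)
        n = 6
        v = squareform(rng.uniform(0.0, 1.0, n * (n - 1) // 2))
        d = se.dissimilarity_index(_dm(v, "combined"))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                mask = np.ones(n, bool)
                mask[[i, j]] = False  # structural entries excluded
                expected = 1.0 - np.corrcoef(v[i, mask], v[j, mask])[0, 1]
                assert d.values[i, j] == pytest.approx(np.clip(expected, 0, 2))

    def test_bounds_and_symmetry_property(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            v = squareform(rng.uniform(0, 1, n * (n - 1) // 2))
            d = se.dissimilarity_index(_dm(v, "combined")).values
            assert np.nanmin(d) >= 0.0 and np.nanmax(d) <= 2.0
            assert np.allclose(d, d.T, equal_nan=True)
            assert np.allclose(np.diag(d), 0.0)


class TestClustering:
    def test_two_separated_types_recovered(self, repertoire):
        rng = np.random.default_rng(0)
        rep = se.make_tutor_repertoire(2, seed=3)
        tracks, truth = [], []
        for ti, tpl in enumerate(rep):
            for j in range(10):
                tr, _ = se.render_rendition(
                    tpl, se.DistortionSpec(delta=0.2, seed=int(rng.integers(2**31))),
                    syllable_id=f"{ti}_{j}")
                tracks.append(tr)
                truth.append(ti)
        d = se.combined_distance(se.summary_table(tracks), tracks, 0.6)
        asg = se.cluster_syllables(d, k=2, enforce_k_range=False)
        tab = pd.crosstab(np.asarray(truth), asg.labels.values)
        assert tab.max(axis=1).sum() == len(truth)  # pure clusters
        assert (tab > 0).sum().sum() == 2

    def test_all_identical_degenerate_flagged(self):
        d = _dm(np.zeros((6, 6)), "dissimilarity_index")
        asg = se.cluster_syllables(d, k=4, enforce_k_range=False)
        assert asg.k == 1
        assert any("degenerate" in m for m in asg.merge_log)

    def test_fewer_points_than_clusters_rejected(self):
        d = _dm(np.zeros((3, 3)), "dissimilarity_index")
        with pytest.raises(ValueError):
            se.cluster_syllables(d, k=4, enforce_k_range=False)

    def test_quality_threshold_marks_unclassified(self):
        rng = np.random.default_rng(7)
        v = squareform(rng.uniform(1.5, 2.0, 15))  # everything far apart
        d = DistanceMatrix(np.clip(v, 0, 2),
                           [f"s{i}" for i in range(6)], "dissimilarity_index")
        asg = se.cluster_syllables(d, k=2, max_scatter=0.1,
                                   enforce_k_range=False)
        assert (asg.labels == UNCLASSIFIED).any()


class TestTutorSimilarity:
    def test_rendition_identical_to_tutor_scores_zero(self, repertoire):
        tutors = se.render_tutor_set(repertoire)
        copy, _ = se.render_rendition(
            repertoire[1], se.DistortionSpec(delta=0.0, seed=1),
            syllable_id="juv_copy")
        other, _ = se.render_rendition(
            repertoire[0], se.DistortionSpec(delta=0.6, seed=2),
            syllable_id="juv_other")
        tracks = tutors + [copy, other]
        d = se.combined_distance(se.summary_table(tracks), tracks, 0.6)
        ts = se.tutor_similarity(d, ["juv_copy", "juv_other"],
                                 [t.type_id for t in repertoire])
        row = ts.set_index("syllable_id").loc["juv_copy"]
        assert row["tutor_similarity"] == pytest.approx(0.0, abs=1e-9)
        assert row["closest_tutor"] == repertoire[1].type_id

    def test_min_over_tutors_regardless_of_cluster(self):
        v = np.array(
            [[0.0, 1.0, 0.2],
             [1.0, 0.0, 0.9],
             [0.2, 0.9, 0.0]]
        )
        d = DistanceMatrix(v, ["t1", "t2", "juv"], "dissimilarity_index")
        ts = se.tutor_similarity(d, ["juv"], ["t1", "t2"])
        assert ts.iloc[0]["closest_tutor"] == "t1"
        assert ts.iloc[0]["tutor_similarity"] == pytest.approx(0.2)

    def test_empty_tutor_set_rejected(self):
        d = _dm(np.zeros((3, 3)), "dissimilarity_index")
        with pytest.raises(ValueError):
            se.tutor_similarity(d, ["s0"], [])


class TestMedianSplit:
    def test_even_count_splits_equally(self):
        s = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        split = se.median_split(s, min_n=2)
        assert (split == "high").sum() == (split == "low").sum() == 5
        assert set(split[s < 5].unique()) == {"high"}

    def test_odd_count_extra_goes_to_high(self):
        s = pd.Series(np.arange(41.0))
        split = se.median_split(s, min_n=40)
        assert (split == "high").sum() == 21
        assert (split == "low").sum() == 20

    def test_below_minimum_renditions_excluded(self):
        s = pd.Series(np.arange(39.0))
        with pytest.raises(ValueError, match="39"):
            se.median_split(s, min_n=40)


class TestPrototypicality:
    def test_medoid_is_most_prototypical_and_outlier_least(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 0.05, size=(7, 2))
        pts[6] = [2.0, 2.0]  # planted outlier
        from scipy.spatial.distance import pdist

        v = np.clip(squareform(pdist(pts)), 0, 2)
        ids = [f"s{i}" for i in range(7)]
        d = DistanceMatrix(v, ids, "dissimilarity_index")
        labels = pd.Series("type_1", index=ids)
        asg = se.ClusterAssignment(labels=labels, k=1)
        proto = se.prototypicality(d, asg)
        assert proto.idxmax() == "s6"
        med = proto.idxmin()
        assert proto[med] == 0.0

    def test_singleton_cluster_scores_zero(self):
        d = _dm(np.zeros((3, 3)), "dissimilarity_index")
        assert se.cluster_scatter(d, ["s0"]) == 0.0

    def test_identical_members_have_zero_scatter(self):
        d = _dm(np.zeros((4, 4)), "dissimilarity_index")
        assert se.cluster_scatter(d, ["s0", "s1", "s2"]) == 0.0
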