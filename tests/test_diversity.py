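"""Alpha/beta diversity, ordination and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from gutomics import diversity as div
from gutomics.preprocess import InputError

from conftest import toy_metadata


def matrix(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestAlphaIndices:
    def test_two_taxon_uniform(self):
        res = div.alpha_indices(matrix({"s": [5, 5]}))
        row = res.loc["s"]
        assert row.richness == 2
        assert row.shannon == pytest.approx(np.log(2))
        assert row.simpson == pytest.approx(0.5)
        assert row.evenness == pytest.approx(1.0)

    def test_single_feature(self):
        row = div.alpha_indices(matrix({"s": [7, 0, 0]})).loc["s"]
        assert row.richness == 1
        assert row.shannon == 0.0
        assert row.simpson == 0.0
        assert np.isnan(row.evenness)

    def test_three_taxon_hand_value(self):
        # p = (0.5, 0.25, 0.25): H = 1.5 ln 2
        row = div.alpha_indices(matrix({"s": [2, 1, 1]})).loc["s"]
        assert row.shannon == pytest.approx(1.5 * np.log(2))

    def test_all_zero_flagged(self):
        row = div.alpha_indices(matrix({"s": [0, 0]})).loc["s"]
        assert row.all_zero and row.richness == 0

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_entropy_bounded_by_log_richness(self, counts):
        res = div.alpha_indices(matrix({"s": counts})).loc["s"]
        if res.richness >= 1:
            assert res.shannon <= np.log(max(res.richness, 1)) + 1e-12
        if res.richness >= 2:
            uniform = len(set(c for c in counts if c > 0)) == 1
            if uniform:
                assert res.evenness == pytest.approx(1.0)
            else:
                assert res.evenness < 1.0 + 1e-12


class TestAlphaLog2fc:
    def test_hand_values(self):
        meta = toy_metadata(n_per_group=2, sexes=("female",))
        vals = pd.Series([2.0, 2.0, 4.0, 4.0], index=meta.index)
        fc, tests = div.alpha_log2fc(vals, meta)
        assert np.allclose(fc.to_numpy(), 1.0)  # log2(4/2)
        assert tests.loc["female", "n_lfd"] == 2

    def test_equal_means_zero(self):
        meta = toy_metadata(n_per_group=2, sexes=("male",))
        vals = pd.Series([3.0, 3.0, 3.0, 3.0], index=meta.index)
        fc, _ = div.alpha_log2fc(vals, meta)
        assert np.allclose(fc.to_numpy(), 0.0)

    def test_zero_reference_flagged(self):
        meta = toy_metadata(n_per_group=2, sexes=("female",))
        vals = pd.Series([0.0, 0.0, 4.0, 4.0], index=meta.index)
        with pytest.warns(UserWarning, match="zero LFD mean"):
            fc, _ = div.alpha_log2fc(vals, meta)
        assert fc.isna().all()


class TestDistances:
    def test_bray_curtis_known_values(self):
        m = matrix({"a": [1, 1], "b": [0, 2], "c": [1, 1], "d": [2, 0]})
        dm = div.bray_curtis(m)
        assert dm["a", "c"] == 0.0
        assert dm["b", "d"] == 1.0  # disjoint supports
        assert dm["a", "b"] == pytest.approx(0.5)

    def test_all_zero_pair_warns_zero(self):
        m = matrix({"a": [0, 0], "b": [0, 0], "c": [1, 2]})
        with pytest.warns(UserWarning, match="all-zero"):
            dm = div.bray_curtis(m)
        assert dm["a", "b"] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            div.bray_curtis(matrix({"a": [-1, 2], "b": [1, 1]}))

    def test_euclidean_pythagoras(self):
        m = matrix({"a": [0, 0], "b": [3, 4]})
        dm = div.euclidean_distance(m, scale="raw")
        assert dm["a", "b"] == pytest.approx(5.0)
        assert dm["a", "a"] == 0.0

    def test_triangle_inequality_random(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.exponential(size=(12, 9)),
                         columns=[f"s{i}" for i in range(9)])
        dm = div.euclidean_distance(m, scale="zlog")
        d = dm.data
        for i in range(9):
            for j in range(9):
                for k in range(9):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_scaling_policy(self):
        m = matrix({"a": [1.0, 10.0], "b": [2.0, 20.0]})
        z = div.scale_metabolites(m, scale="zlog")
        assert np.allclose(z.mean(axis=1), 0.0)
        with pytest.raises(InputError):
            div.scale_metabolites(m, scale="nope")


class TestPcoa:
    def test_collinear_points_exact_embedding(self):
        # mutual distances 1, 1, 2 embed exactly on a line
        dm = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=list("abc"))
        res = div.pcoa(dm)
        coords = res.samples.to_numpy()
        rec = squareform(pdist(coords))
        assert np.allclose(rec, dm.data, atol=1e-8)

    def test_duplicate_samples_identical_coordinates(self):
        pts = np.array([[0.0, 0], [0, 0], [3, 4], [1, 1]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        res = div.pcoa(dm)
        c = res.samples.to_numpy()
        assert np.allclose(c[0], c[1], atol=1e-8)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(10)])
        res = div.pcoa(dm)
        rec = squareform(pdist(res.samples.to_numpy()))
        assert np.max(np.abs(rec - dm.data)) < 1e-8

    def test_truncation_warns(self):
        dm = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=list("abc"))
        with pytest.warns(UserWarning, match="truncating"):
            res = div.pcoa(dm, n_axes=3)


class TestPermanova:
    def toy(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        d = np.abs(pts[:, None] - pts[None, :])
        return DistanceMatrix(d, ids=list("abcd")), np.array(["g1", "g1", "g2", "g2"])

    def test_hand_computed_f_and_exhaustive_p(self):
        dm, labels = self.toy()
        res = div.permanova(dm, labels)
        assert res.pseudo_f == pytest.approx(200.0)
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "exhaustive"
        assert 0 < res.r_squared < 1

    def test_identical_groups_no_separation(self):
        pts = np.array([0.0, 1.0, 0.0, 1.0])
        d = np.abs(pts[:, None] - pts[None, :])
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = div.permanova(dm, ["g1", "g1", "g2", "g2"])
        assert res.p_value > 0.5

    def test_small_group_rejected(self):
        dm, _ = self.toy()
        with pytest.raises(InputError):
            div.permanova(dm, ["g1", "g1", "g1", "g2"])

    def test_monte_carlo_matches_exhaustive(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        pts[4:] += 1.0
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        ex = div.permanova(dm, labels, exhaustive=True)
        b = 4000
        mc = div.permanova(dm, labels, n_permutations=b, seed=3, exhaustive=False)
        se = np.sqrt(ex.p_value * (1 - ex.p_value) / b)
        assert mc.pseudo_f == pytest.approx(ex.pseudo_f)
        assert abs(mc.p_value - ex.p_value) <= 3 * se + 1 / (b + 1)

    def test_cross_check_against_independent_implementation(self):
        """pseudo-F and MC p agree with the scikit-bio PERMANOVA."""
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(16, 5))
        pts[8:, 0] += 1.5
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(16)])
        labels = ["a"] * 8 + ["b"] * 8
        ours = div.permanova(dm, labels, n_permutations=999, seed=5, exhaustive=False)
        ref = skbio_permanova(dm, grouping=labels, permutations=999)
        assert ours.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-9)
        assert abs(ours.p_value - float(ref["p-value"])) < 0.05


class TestDistanceSets:
    def seg_dm(self):
        rng = np.random.default_rng(6)
        # proximal cluster far from distal cluster
        segs, pts = [], []
        for i, seg in enumerate(["duodenojejunum", "jejunum", "proximal_colon", "feces"]):
            base = 0.0 if i < 2 else 8.0
            for j in range(4):
                pts.append(rng.normal(base + 0.2 * i, 0.3, size=3))
                segs.append(seg)
        ids = [f"s{i}" for i in range(len(pts))]
        dm = DistanceMatrix(squareform(pdist(np.array(pts))), ids=ids)
        return dm, pd.Series(segs, index=ids)

    def test_classes_and_separation(self):
        dm, segs = self.seg_dm()
        pair_d, comps = div.distance_class_compare(dm, segs, n_perm=199, seed=0)
        by_class = pair_d.groupby("distance_class")["mean"].mean()
        assert by_class["mixed"] > by_class["small_intestine"]
        assert by_class["mixed"] > by_class["distal"]
        assert (comps["p_holm"] >= comps["p"] - 1e-12).all()

    def test_unknown_segment_rejected(self):
        dm, segs = self.seg_dm()
        bad = segs.copy()
        bad.iloc[0] = "stomach"
        with pytest.raises(InputError):
            div.distance_class_compare(dm, bad)

    def test_two_segments_single_comparison(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 2))
        ids = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        segs = pd.Series(["jejunum"] * 4 + ["feces"] * 4, index=ids)
        pair_d, comps = div.distance_class_compare(dm, segs)
        assert len(pair_d) == 1 and len(comps) == 0

    def test_degenerate_distances_flagged(self):
        d = np.ones((6, 6)) - np.eye(6)
        ids = [f"s{i}" for i in range(6)]
        dm = DistanceMatrix(d, ids=ids)
        segs = pd.Series(["duodenojejunum", "duodenojejunum", "jejunum",
                          "jejunum", "ileum", "ileum"], index=ids)
        _, comps = div.distance_class_compare(dm, segs)
        assert comps["degenerate"].all()
        assert (comps["p"] == 1.0).all()


class TestIntraInter:
    def test_tight_far_clusters(self):
        pts = np.vstack([np.zeros((4, 2)), np.full((4, 2), 10.0)])
        pts += np.random.default_rng(8).normal(0, 0.1, pts.shape)
        ids = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        groups = pd.Series(["g1"] * 4 + ["g2"] * 4, index=ids)
        within, between, tests = div.intra_inter_group_distances(dm, groups)
        assert between[("g1", "g2")].min() > max(within["g1"].max(), within["g2"].max())

    def test_singleton_group_flagged(self):
        pts = np.random.default_rng(9).normal(size=(5, 2))
        ids = [f"s{i}" for i in range(5)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        groups = pd.Series(["g1"] * 4 + ["g2"], index=ids)
        within, between, tests = div.intra_inter_group_distances(dm, groups)
        assert len(within["g2"]) == 0
        assert np.isnan(tests["p_within_vs_within"]).all()

    def test_random_labels_similar_distributions(self):
        rng = np.random.default_rng(10)
        ok = 0
        for rep in range(20):
            pts = rng.normal(size=(16, 3))
            ids = [f"s{i}" for i in range(16)]
            dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
            labels = np.array(["g1"] * 8 + ["g2"] * 8)
            rng.shuffle(labels)
            groups = pd.Series(labels, index=ids)
            _, _, tests = div.intra_inter_group_distances(dm, groups)
            if tests["p_within_vs_within"].iloc[0] > 0.01:
                ok += 1
        assert ok >= 15  # under the null, small p is rare
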