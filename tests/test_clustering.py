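"""Cluster identification: seeding, merging, circular statistics."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from porestate.clustering import (cluster_conformations, cluster_stats, embed,
                                  hierarchical_merge, kmeans_gate,
                                  mean_shift_seed, representative_frame)
from porestate.synthetic import gen_state_trajectory


class TestKmeansGate:
    def test_single_cluster_centroid_is_mean(self, rng):
        X = rng.normal(size=(40, 3))
        cs = kmeans_gate(features=X, k=1, seed=0)
        assert np.allclose(cs.centroids["a"], X.mean(axis=0))
        assert set(cs.labels) == {"a"}

    def test_two_planted_states_pure_partition(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (60, 2)),
                       rng.normal(8, 0.2, (40, 2))])
        truth = np.r_[np.zeros(60, int), np.ones(40, int)]
        cs = kmeans_gate(features=X, k=2, seed=0)
        for lab in "ab":
            m = cs.labels == lab
            assert np.bincount(truth[m]).max() == m.sum()    # purity 1
        # labels ordered by size: 'a' is the 60-member cluster
        assert (cs.labels == "a").sum() == 60

    def test_duplication_preserves_structure(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (30, 2)),
                       rng.normal(5, 0.2, (30, 2))])
        a = kmeans_gate(features=X, k=2, seed=1)
        b = kmeans_gate(features=np.vstack([X, X]), k=2, seed=1)
        assert np.array_equal(b.labels[:60], b.labels[60:])
        assert sorted(b.summary["size"]) == [2 * s for s in
                                             sorted(a.summary["size"])]

    def test_coordinate_mode_rmsd_metric(self, rng):
        # two rigid shapes; rotated copies must cluster with their parents
        from scipy.spatial.transform import Rotation
        base1 = rng.normal(size=(10, 3))
        base2 = base1 + np.array([0.0, 0.0, 4.0]) * rng.normal(1, 0.1, (10, 1))
        frames = []
        truth = []
        for i in range(20):
            R = Rotation.random(random_state=i).as_matrix()
            src = base1 if i % 2 == 0 else base2
            frames.append(src @ R.T + rng.normal(0, 0.01, (10, 3)))
            truth.append(i % 2)
        cs = kmeans_gate(coords=np.array(frames), k=2, seed=0)
        truth = np.array(truth)
        for lab in "ab":
            m = cs.labels == lab
            assert np.bincount(truth[m]).max() == m.sum()

    def test_k_exceeding_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_gate(features=rng.normal(size=(5, 2)), k=10)


class TestEmbed:
    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(120, 5))
        a = embed(X, perplexity=10, seed=3)
        b = embed(X, perplexity=10, seed=3)
        assert np.array_equal(a, b)

    def test_degenerate_input_warns(self):
        X = np.ones((50, 4))
        with pytest.warns(UserWarning, match="degenerate"):
            out = embed(X, perplexity=5)
        assert out.shape == (50, 2) and np.all(out == 0)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            embed(rng.normal(size=(20, 3)), perplexity=30)

    def test_wrapped_angle_state_stays_in_one_cluster(self, rng):
        # a state straddling +-180: sin/cos encoding keeps it together
        from porestate.features import FeatureScaler
        angles = np.where(rng.random(200) < 0.5, 178.0, -178.0)
        angles += rng.normal(0, 1.0, 200)
        d = rng.normal(10.0, 0.1, 200)
        df = pd.DataFrame({"chi": angles, "d": d})
        X, _ = FeatureScaler(angle_cols=("chi",)).fit_transform(df)
        emb = embed(X, perplexity=15, seed=0)
        from porestate.clustering import default_bandwidth
        bw = default_bandwidth(emb, 0.1)
        cents, lab = mean_shift_seed(emb, bw)
        merged = hierarchical_merge(emb, lab, cents, 12 * bw, 2 * bw)
        assert len(np.unique(merged)) == 1


class TestMeanShift:
    def test_single_blob_one_centroid_at_mean(self, rng):
        P = rng.normal(0, 0.3, size=(200, 2))
        cents, lab = mean_shift_seed(P, bandwidth=3.0)
        assert len(cents) == 1
        assert np.allclose(cents[0], P.mean(axis=0), atol=1e-6)

    def test_two_distant_blobs(self, rng):
        P = np.vstack([rng.normal(0, 0.3, (100, 2)),
                       rng.normal(10, 0.3, (100, 2))])
        cents, lab = mean_shift_seed(P, bandwidth=1.0)
        assert len(cents) == 2
        assert len(np.unique(lab[:100])) == 1
        assert lab[0] != lab[150]

    def test_modes_match_hill_climb_oracle(self, rng):
        P = np.vstack([rng.normal((0, 0), 0.4, (80, 2)),
                       rng.normal((6, 2), 0.4, (80, 2)),
                       rng.normal((0, 7), 0.4, (80, 2))])
        bw = 1.5
        cents, lab = mean_shift_seed(P, bandwidth=bw)

        def climb(p):   # independent per-point flat-kernel ascent
            x = p.copy()
            for _ in range(500):
                nb = P[np.linalg.norm(P - x, axis=1) <= bw]
                nxt = nb.mean(axis=0)
                if np.linalg.norm(nxt - x) < 1e-7:
                    break
                x = nxt
            return x

        for i in range(0, len(P), 17):
            mode = climb(P[i])
            assert np.linalg.norm(cents[lab[i]] - mode) < bw / 2

    def test_nonpositive_bandwidth_rejected(self, rng):
        with pytest.raises(ValueError):
            mean_shift_seed(rng.normal(size=(10, 2)), 0.0)


class TestHierarchicalMerge:
    def _three(self, rng, gap):
        blobs = [rng.normal((0, 0), 0.2, (30, 2)),
                 rng.normal((gap, 0), 0.2, (20, 2)),
                 rng.normal((2 * gap, 0), 0.2, (10, 2))]
        P = np.vstack(blobs)
        lab = np.r_[np.zeros(30, int), np.ones(20, int), np.full(10, 2)]
        cents = np.array([b.mean(axis=0) for b in blobs])
        return P, lab, cents

    def test_distant_clusters_unchanged(self, rng):
        P, lab, cents = self._three(rng, 10.0)
        merged = hierarchical_merge(P, lab, cents, centroid_cutoff=2.0,
                                    point_cutoff=1.0)
        assert len(np.unique(merged)) == 3

    def test_close_pair_merges(self, rng):
        P, lab, cents = self._three(rng, 10.0)
        # move cluster 1 next to cluster 0
        P[30:50] -= [8.9, 0.0]
        cents[1] -= [8.9, 0.0]
        merged = hierarchical_merge(P, lab, cents, centroid_cutoff=2.0,
                                    point_cutoff=1.0)
        assert len(np.unique(merged)) == 2

    def test_chain_merge_is_transitive(self, rng):
        P, lab, cents = self._three(rng, 1.5)    # A-B close, B-C close
        merged = hierarchical_merge(P, lab, cents, centroid_cutoff=2.0,
                                    point_cutoff=1.2)
        # A and C are 3.0 apart (beyond the centroid cutoff) yet united via B
        assert len(np.unique(merged)) == 1

    def test_never_increases_cluster_count(self, rng):
        P, lab, cents = self._three(rng, 4.0)
        merged = hierarchical_merge(P, lab, cents, 1.0, 0.5)
        assert len(np.unique(merged)) <= len(cents)

    def test_labels_alphabetic_by_size(self, rng):
        P, lab, cents = self._three(rng, 10.0)
        merged = hierarchical_merge(P, lab, cents, 1.0, 0.5)
        sizes = [np.sum(merged == l) for l in ("a", "b", "c")]
        assert sizes == sorted(sizes, reverse=True) == [30, 20, 10]


class TestClusterStats:
    def test_wraparound_mean(self):
        df = pd.DataFrame({"chi": [359.0, 1.0]})
        st = cluster_stats(df, np.array(["a", "a"]), angle_cols=("chi",))
        assert st.loc[0, "chi_mean"] == pytest.approx(0.0, abs=1e-9)

    def test_single_member_sd_zero(self):
        df = pd.DataFrame({"chi": [90.0]})
        st = cluster_stats(df, np.array(["a"]), angle_cols=("chi",))
        assert st.loc[0, "chi_mean"] == pytest.approx(90.0)
        assert st.loc[0, "chi_sd"] == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_circular_sd(self):
        df = pd.DataFrame({"chi": [0.0, 90.0]})
        st = cluster_stats(df, np.array(["a", "a"]), angle_cols=("chi",))
        expect = np.degrees(np.sqrt(-2.0 * np.log(np.cos(np.radians(45.0)))))
        assert st.loc[0, "chi_mean"] == pytest.approx(45.0, abs=1e-9)
        assert st.loc[0, "chi_sd"] == pytest.approx(expect, abs=1e-9)

    def test_matches_scipy_circular_stats(self, rng):
        a = rng.uniform(-180, 180, 500)
        df = pd.DataFrame({"chi": a})
        st = cluster_stats(df, np.array(["a"] * 500), angle_cols=("chi",))
        assert st.loc[0, "chi_mean"] == pytest.approx(
            sps.circmean(a, high=180, low=-180), abs=1e-9)
        assert st.loc[0, "chi_sd"] == pytest.approx(
            np.degrees(sps.circstd(np.radians(a))), abs=1e-9)

    def test_stats_use_only_member_rows(self, rng):
        df = pd.DataFrame({"d": np.r_[np.full(50, 1.0), rng.normal(99, 1, 50)]})
        lab = np.array(["a"] * 50 + ["b"] * 50)
        st = cluster_stats(df, lab)
        assert st.set_index("label").loc["a", "d_mean"] == pytest.approx(1.0)


class TestRepresentativeFrame:
    def test_singleton_cluster(self):
        df = pd.DataFrame({"d": [3.0]})
        assert representative_frame(df, np.array(["a"]), "a") == 0

    def test_tie_breaks_to_earliest(self):
        df = pd.DataFrame({"d": [1.0, 3.0]})    # both 1.0 from the mean 2.0
        assert representative_frame(df, np.array(["a", "a"]), "a") == 0

    def test_matches_exhaustive_scan(self, rng):
        from porestate._geom import circ_mean_deg, wrap_deg
        chi = rng.uniform(-180, 180, 100)
        d = rng.normal(15, 1, 100)
        df = pd.DataFrame({"chi": chi, "d": d})
        lab = np.array(["a"] * 100)
        got = representative_frame(df, lab, "a", angle_cols=("chi",))
        mc, md = circ_mean_deg(chi), d.mean()
        dist = np.hypot(wrap_deg(chi - mc), d - md)
        assert got == int(np.argmin(dist))

    def test_empty_cluster_rejected(self):
        df = pd.DataFrame({"d": [1.0]})
        with pytest.raises(ValueError):
            representative_frame(df, np.array(["a"]), "z")


class TestEndToEnd:
    def test_four_planted_states_recovered(self):
        """One-seed version of the full recovery experiment (incl. a state
        at the chi1 = 180 wrap)."""
        C = np.array([[-60.0, -60.0, 12.0], [60.0, 60.0, 15.0],
                      [180.0, 180.0, 18.0], [-170.0, -170.0, 21.0]])
        mask = np.array([True, True, False])
        noise = np.array([8.0, 8.0, 0.25])
        T = np.full((4, 4), 0.005 / 3)
        np.fill_diagonal(T, 0.995)
        feats, truth = gen_state_trajectory(C, T, 1200, noise, mask, seed=0)
        df = pd.DataFrame(feats, columns=["chi1_A", "chi1_B", "d625"])
        cs, emb = cluster_conformations(df, angle_cols=("chi1_A", "chi1_B"),
                                        perplexity=30, seed=0)
        assert len(cs.cluster_ids) == 4
        purity = sum(np.bincount(truth[cs.labels == l]).max()
                     for l in cs.cluster_ids) / len(truth)
        assert purity >= 0.95
        # summary bookkeeping reconciles with the labels
        for _, row in cs.summary.iterrows():
            assert row["size"] == np.sum(cs.labels == row["label"])
            assert cs.labels[row["representative_frame"]] == row["label"]
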