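import math

import numpy as np
import pytest

from lesiondyn import (ClassifiedLesion, build_ctls, choose_k_elbow,
                       cluster_cc, cluster_report, elbow_k_from_sse,
                       interclass_pairs, intraclass_pairs, kmeans_1d,
                       similar_share, sse_curve)
from lesiondyn.crosscorr import CCRecord
from _oracles import exhaustive_kmeans_1d
from conftest import series


class TestBuildCtls:
    def test_sums_lesions_of_a_class(self):
        lesions = {"L1": series("P", "L1", [0, 8], [30, 20]),
                   "L2": series("P", "L2", [0, 8], [10, 5])}
        ctls = build_ctls(lesions, {"L1": "Liver", "L2": "Liver"})
        assert list(ctls["Liver"].sizes) == [40.0, 25.0]

    def test_complete_case_visit_rule(self):
        lesions = {"A": series("P", "A", [0, 8, 16], [30, 20, 10]),
                   "B": series("P", "B", [0, 8], [10, 5])}
        ctls = build_ctls(lesions, {"A": "Liver", "B": "Liver"})
        # oracle: brute-force intersection of visit sets
        want_times = sorted(set([0, 8, 16]) & set([0, 8]))
        assert list(ctls["Liver"].times) == [float(t) for t in want_times]
        assert list(ctls["Liver"].sizes) == [40.0, 25.0]

    def test_single_lesion_class_is_identity(self):
        lesions = {"A": series("P", "A", [0, 8, 16], [30, 20, 10])}
        ctls = build_ctls(lesions, {"A": "Lung"})
        assert list(ctls["Lung"].sizes) == [30.0, 20.0, 10.0]

    def test_classes_with_fewer_than_two_visits_dropped(self):
        lesions = {"A": series("P", "A", [0, 8], [30, 20]),
                   "B": series("P", "B", [16], [9])}
        ctls = build_ctls(lesions, {"A": "Liver", "B": "Lung"})
        assert set(ctls) == {"Liver"}


class TestPairEnumeration:
    def _ctls(self, n_classes):
        return {f"C{i}": series("P", f"C{i}", [0, 8], [30 + i, 20])
                for i in range(n_classes)}

    def test_three_classes_three_pairs(self):
        recs = interclass_pairs({"P": self._ctls(3)})
        assert len(recs) == 3
        assert all(r.kind == "inter" for r in recs)

    def test_single_class_patient_excluded(self):
        assert interclass_pairs({"P": self._ctls(1)}) == []

    def test_two_patients_two_classes_each(self):
        ctls = {"P1": self._ctls(2), "P2": self._ctls(2)}
        assert len(interclass_pairs(ctls)) == 2

    @pytest.mark.parametrize("n,expected", [(1, 0), (3, 3), (5, 10)])
    def test_intraclass_pair_counts(self, n, expected):
        lesions = {f"L{i}": series("P", f"L{i}", [0, 8], [30 + i, 20 - i])
                   for i in range(n)}
        classified = {"P": {lid: ClassifiedLesion("P", lid, "Liver")
                            for lid in lesions}}
        recs = intraclass_pairs({"P": lesions}, classified, "Liver")
        assert len(recs) == expected
        assert intraclass_pairs({"P": lesions}, classified, "Lung") == []


class TestKmeans1d:
    def test_recovers_three_tight_groups(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([
            -0.9 + 0.01 * rng.standard_normal(100),
            0.0 + 0.01 * rng.standard_normal(100),
            0.9 + 0.01 * rng.standard_normal(100)])
        res = kmeans_1d(vals, 3, seed=0)
        assert res.centroids == pytest.approx([-0.9, 0.0, 0.9], abs=0.01)
        # exact membership: cluster index equals the generating block
        assert (res.labels[:100] == 0).all()
        assert (res.labels[100:200] == 1).all()
        assert (res.labels[200:] == 2).all()
        best_sse, _ = exhaustive_kmeans_1d(vals.tolist(), 3)
        assert res.sse == pytest.approx(best_sse, rel=1e-9)

    def test_k1_closed_form(self):
        vals = np.array([1.0, 2.0, 4.0, 9.0])
        res = kmeans_1d(vals, 1)
        assert res.centroids[0] == pytest.approx(vals.mean())
        assert res.sse == pytest.approx(((vals - vals.mean()) ** 2).sum())

    def test_duplicates_k_equals_distinct_gives_zero_sse(self):
        vals = [0.2, 0.2, 0.7, 0.7, -0.5, -0.5]
        res = kmeans_1d(vals, 3, seed=1)
        assert res.sse == pytest.approx(0.0, abs=1e-15)
        assert sorted(res.centroids) == pytest.approx([-0.5, 0.2, 0.7])

    def test_k_above_distinct_count_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_1d([0.1, 0.1, 0.9], 3)

    def test_same_seed_reproduces_bitwise(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(-1, 1, 200)
        a = kmeans_1d(vals, 3, seed=9)
        b = kmeans_1d(vals, 3, seed=9)
        assert (a.labels == b.labels).all()
        assert a.sse == b.sse
        assert (a.centroids == b.centroids).all()

    @pytest.mark.parametrize("n,k", [(8, 2), (10, 3), (12, 4)])
    def test_matches_exhaustive_partitioning_on_small_sets(self, n, k):
        rng = np.random.default_rng(n * 7 + k)
        for _ in range(20):
            vals = np.round(rng.uniform(-1, 1, n), 3)
            res = kmeans_1d(vals, k, seed=0)
            best_sse, best_parts = exhaustive_kmeans_1d(vals.tolist(), k)
            assert res.sse == pytest.approx(best_sse, abs=1e-10)


class TestElbow:
    def test_hand_computed_log_curvature(self):
        # log-SSE second differences: k=2: 4.0-2*3.0+1.0 = -1.0;
        # k=3: 3.0-2*1.0+0.8 = 1.8; k=4: 1.0-1.6+0.7 = 0.1  -> k=3
        sse = np.exp([4.0, 3.0, 1.0, 0.8, 0.7])
        assert elbow_k_from_sse(sse) == 3

    def test_trimodal_sample_selects_three(self):
        rng = np.random.default_rng(123)
        vals = np.repeat([-0.9, 0.15, 0.9], 300) + 0.05 * rng.standard_normal(900)
        assert choose_k_elbow(np.clip(vals, -1, 1), k_max=6, seed=0) == 3

    def test_single_mode_returns_curvature_argmax(self):
        rng = np.random.default_rng(7)
        vals = 0.2 + 0.05 * rng.standard_normal(400)
        k = choose_k_elbow(vals, k_max=6, seed=0)
        sse = sse_curve(vals, 6, seed=0)
        assert k == elbow_k_from_sse(sse)
        assert 2 <= k <= 5

    def test_sse_curve_non_increasing(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(-1, 1, 100)
        sse = sse_curve(vals, 6, seed=0)
        assert (np.diff(sse) <= 1e-9).all()

    def test_few_distinct_values_shrinks_k_max_with_warning(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5]
        with pytest.warns(UserWarning, match="shrunk"):
            k = choose_k_elbow(vals, k_max=6, seed=0)
        assert 2 <= k <= 3


def _cc(pid, v, lag=0, vmax=None):
    vmax = v if vmax is None else vmax
    return CCRecord(pid, "a", "b", v, vmax, lag, 4, {0: v})


class TestClusterReport:
    def test_labels_follow_centroid_cutoffs(self):
        recs = ([_cc(f"P{i}", -0.97 + 0.001 * i) for i in range(5)]
                + [_cc(f"Q{i}", 0.2 + 0.001 * i) for i in range(5)]
                + [_cc(f"R{i}", 0.9 + 0.001 * i) for i in range(5)])
        res, kept = cluster_cc(recs, k=3, seed=0)
        rep, hist = cluster_report(res, kept)
        assert list(rep["label"]) == ["different", "undefined", "similar"]
        assert rep["pct_pairs"].sum() == pytest.approx(100.0, abs=0.1)

    def test_patient_in_two_clusters_counted_twice(self):
        recs = [_cc("P1", -0.9), _cc("P1", 0.9), _cc("P2", 0.91),
                _cc("P3", -0.91), _cc("P4", 0.05)]
        res, kept = cluster_cc(recs, k=3, seed=0)
        rep, _ = cluster_report(res, kept)
        # P1 appears in both cluster 1 and cluster 3
        assert rep["pct_patients"].sum() > 100.0
        assert rep.loc[rep.cluster == 1, "n_patients"].item() == 2
        assert rep.loc[rep.cluster == 3, "n_patients"].item() == 2

    def test_undefined_ccs_excluded(self):
        recs = [_cc("P1", -0.9), _cc("P2", 0.9),
                CCRecord("P3", "a", "b", float("nan"), float("nan"), 0, 1, {})]
        res, kept = cluster_cc(recs, k=2, seed=0)
        assert res.n == 2
        assert len(kept) == 2

    def test_lag_histogram_counts(self):
        recs = [_cc("P1", 0.9, lag=0), _cc("P2", 0.91, lag=1),
                _cc("P3", 0.92, lag=1), _cc("P4", -0.9, lag=0)]
        res, kept = cluster_cc(recs, k=2, seed=0)
        _, hist = cluster_report(res, kept)
        high = hist[hist.cluster == 2].set_index("lag")["count"]
        assert high.to_dict() == {0: 1, 1: 2}

    def test_similar_share_merges_high_centroid_clusters(self):
        recs = ([_cc(f"P{i}", 0.55 + 0.001 * i) for i in range(4)]
                + [_cc(f"Q{i}", 0.95 - 0.001 * i) for i in range(4)]
                + [_cc(f"R{i}", -0.9 + 0.001 * i) for i in range(4)])
        res, kept = cluster_cc(recs, k=3, seed=0)
        rep, _ = cluster_report(res, kept)
        assert similar_share(rep) == pytest.approx(
            rep.loc[rep.centroid > 0.35, "pct_pairs"].sum())
        assert similar_share(rep) == pytest.approx(200.0 / 3, abs=0.1)
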