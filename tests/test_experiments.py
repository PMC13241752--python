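import numpy as np
import pandas as pd
import pytest

from periwound import supervised, unsupervised
from periwound.io_config import AnnotationTable, RunConfig
from periwound.synthetic import ARCHETYPES, identity_annotator, simulate_annotations


def _table(labels_per_rater):
    n = len(next(iter(labels_per_rater.values())))
    return AnnotationTable(
        pd.DataFrame(
            labels_per_rater,
            index=pd.Index([f"img_{i}" for i in range(n)], name="image_id"),
        ),
        merged=True,
    )


def _blob_data(n_per_class, k, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, (k, 4))
    x = np.vstack([c + rng.normal(0, 0.5, (n_per_class, 4)) for c in centers])
    y = np.repeat([ARCHETYPES[i % 5] for i in range(k)], n_per_class)
    return x, y


class TestReduce:
    def test_planar_data_reconstructed_exactly(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        coords = rng.normal(size=(100, 2))
        x = coords @ basis
        emb = unsupervised.reduce(x, "pca", dims=2, seed=0)
        # rank-2 data: 2 components carry all variance
        assert np.var(x, axis=0).sum() == pytest.approx(
            np.var(emb, axis=0).sum(), rel=1e-9
        )

    def test_full_rank_pca_preserves_distances(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 5))
        emb = unsupervised.reduce(x, "pca", dims=5, seed=0)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(x), pdist(emb), atol=1e-9)

    def test_umap_deterministic_given_seed(self):
        x, _ = _blob_data(20, 3, seed=2)
        a = unsupervised.reduce(x, "umap", dims=2, seed=5)
        b = unsupervised.reduce(x, "umap", dims=2, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_constant_matrix_rejected(self):
        with pytest.raises(unsupervised.DegenerateVarianceError):
            unsupervised.reduce(np.ones((20, 4)), "pca", 2, 0)


class TestCluster:
    def test_separated_blobs_fully_recovered(self):
        x, y = _blob_data(30, 3, seed=3)
        labels = unsupervised.cluster(x, 3, seed=0)
        from periwound.agreement import align_labels

        _, relabeled = align_labels(labels, y)
        assert (relabeled == y).mean() == 1.0

    def test_duplicated_rows_get_identical_labels(self):
        x, _ = _blob_data(10, 2, seed=4)
        xx = np.vstack([x, x])
        labels = unsupervised.cluster(xx, 2, seed=0)
        np.testing.assert_array_equal(labels[: len(x)], labels[len(x) :])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            unsupervised.cluster(np.zeros((3, 2)), 5, 0)


class TestEvaluateUnsupervised:
    def test_clusters_equal_to_one_rater(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(ARCHETYPES, 200)
        cluster_ids = np.array([ARCHETYPES.index(v) for v in labels])
        table = _table({"e1": labels})
        res = unsupervised.evaluate_unsupervised(cluster_ids, table)
        assert res.kappa_per_rater["e1"] == 1.0
        assert res.ari == 1.0

    def test_random_clusters_near_chance(self):
        rng = np.random.default_rng(6)
        labels = rng.choice(ARCHETYPES, 10_000)
        clusters = rng.integers(0, 5, 10_000)
        res = unsupervised.evaluate_unsupervised(clusters, _table({"e1": labels}))
        assert abs(res.kappa_per_rater["e1"]) < 0.03
        assert abs(res.ari) < 0.03

    def test_ari_single_code_path(self):
        from periwound.agreement import adjusted_rand

        rng = np.random.default_rng(7)
        labels = rng.choice(ARCHETYPES, 100)
        clusters = rng.integers(0, 5, 100)
        res = unsupervised.evaluate_unsupervised(clusters, _table({"e1": labels}))
        assert res.ari == adjusted_rand(clusters, labels)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            unsupervised.evaluate_unsupervised(
                np.zeros(5, int), _table({"e1": ["attached"] * 6})
            )


class TestTrainEval:
    CFG = RunConfig(cv_folds=3, cv_repeats=2)

    def _features(self, x, extra_visual=None):
        cols = {f"g{i}": x[:, i] for i in range(x.shape[1])}
        groups = {f"g{i}": "geometry" for i in range(x.shape[1])}
        if extra_visual is not None:
            for i in range(extra_visual.shape[1]):
                cols[f"v{i}"] = extra_visual[:, i]
                groups[f"v{i}"] = "visual"
        df = pd.DataFrame(
            cols, index=pd.Index([f"img_{i}" for i in range(len(x))], name="image_id")
        )
        return df, groups

    def test_separable_features_recover_rater_labels(self):
        x, y = _blob_data(40, 5, seed=8)
        df, groups = self._features(x)
        table = simulate_annotations(
            list(y), [identity_annotator("e1"), identity_annotator("e2")], seed=0,
            image_ids=list(df.index),
        )
        rep = supervised.train_eval(
            df, groups, table, "geometry", self.CFG, seed=0, compute_importances=False
        )
        for rater in rep.raters:
            assert rep.per_rater[rater].kappa_mean >= 0.95

    def test_shuffled_labels_give_chance_kappa(self):
        rng = np.random.default_rng(9)
        x, y = _blob_data(200, 5, seed=10)
        shuffled = rng.permutation(y)
        df, groups = self._features(x)
        table = _table({"e1": shuffled})
        rep = supervised.train_eval(
            df, groups, table, "geometry", self.CFG, seed=0, compute_importances=False
        )
        assert abs(rep.kappa_mean) < 0.05

    def test_geometry_set_sees_only_geometry_columns(self):
        x, y = _blob_data(20, 3, seed=11)
        rng = np.random.default_rng(12)
        df, groups = self._features(x, extra_visual=rng.normal(size=(len(x), 3)))
        table = _table({"e1": y})
        rep = supervised.train_eval(
            df, groups, table, "geometry", self.CFG, seed=0, compute_importances=False
        )
        assert rep.columns == [c for c in df.columns if groups[c] == "geometry"]
        full = supervised.train_eval(
            df, groups, table, "full", self.CFG, seed=0, compute_importances=False
        )
        assert full.columns == list(df.columns)

    def test_run_count_matches_repeats_times_raters(self):
        x, y = _blob_data(20, 5, seed=13)
        df, groups = self._features(x)
        table = simulate_annotations(
            list(y), [identity_annotator("e1"), identity_annotator("e2")], seed=1,
            image_ids=list(df.index),
        )
        rep = supervised.train_eval(
            df, groups, table, "geometry", self.CFG, seed=0, compute_importances=False
        )
        assert len(rep.runs) == self.CFG.cv_repeats * len(rep.raters)

    def test_importances_normalized(self):
        x, y = _blob_data(40, 3, seed=14)
        df, groups = self._features(x)
        rep = supervised.train_eval(
            df, groups, _table({"e1": y}), "geometry", self.CFG, seed=0
        )
        assert sum(rep.importances.values()) == pytest.approx(1.0)


class TestCompareFeatureSets:
    def test_identical_reports_not_significant(self):
        x, y = _blob_data(30, 5, seed=15)
        df = pd.DataFrame(
            {f"g{i}": x[:, i] for i in range(4)},
            index=pd.Index([f"img_{i}" for i in range(len(x))], name="image_id"),
        )
        groups = {f"g{i}": "geometry" for i in range(4)}
        table = _table({"e1": y})
        cfg = RunConfig(cv_folds=3, cv_repeats=2)
        rep = supervised.train_eval(
            df, groups, table, "geometry", cfg, seed=0, compute_importances=False
        )
        out = supervised.compare_feature_sets(rep, rep)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_mismatched_runs_rejected(self):
        x, y = _blob_data(30, 5, seed=16)
        df = pd.DataFrame(
            {"g0": x[:, 0], "g1": x[:, 1]},
            index=pd.Index([f"img_{i}" for i in range(len(x))], name="image_id"),
        )
        groups = {"g0": "geometry", "g1": "geometry"}
        table = _table({"e1": y})
        rep2 = supervised.train_eval(
            df, groups, table, "geometry", RunConfig(cv_folds=3, cv_repeats=2),
            seed=0, compute_importances=False,
        )
        rep3 = supervised.train_eval(
            df, groups, table, "geometry", RunConfig(cv_folds=3, cv_repeats=3),
            seed=0, compute_importances=False,
        )
        with pytest.raises(ValueError):
            supervised.compare_feature_sets(rep2, rep3)
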