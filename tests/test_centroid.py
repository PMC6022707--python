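import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

import famclust as fc
from oracles import spearman_oracle


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return fc.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        platform="intensity",
        transform_state="zscored",
    )


class TestSpearman:
    def test_monotone_agreement_is_one(self):
        assert fc.spearman([1, 5, 9, 11], [0.1, 0.2, 0.5, 0.9]) == pytest.approx(1.0)

    def test_reversed_order_is_minus_one(self):
        assert fc.spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_pair_midrank_value(self):
        # ranks (1, 2.5, 2.5, 4) vs (1, 2, 3, 4)
        assert fc.spearman([1, 2, 2, 3], [1, 2, 3, 4]) == pytest.approx(0.9487, abs=1e-4)

    def test_matches_midrank_oracle_on_random_vectors(self, rng):
        for _ in range(25):
            x = rng.integers(0, 6, size=12).astype(float)  # many ties
            y = rng.normal(size=12)
            if np.ptp(x) == 0:
                continue
            assert fc.spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_constant_vector_rejected_not_zero(self):
        with pytest.raises(fc.ValidationError):
            fc.spearman([1, 1, 1], [1, 2, 3])

    def test_short_vector_rejected(self):
        with pytest.raises(fc.ValidationError):
            fc.spearman([1, 2], [3, 4])


class TestTrainCentroids:
    def test_duplicated_profile_centroid_is_the_profile(self):
        v = [1.0, -2.0, 0.5]
        expr = _expr(np.array([v, v, [0.0, 0.0, 1.0], [0.1, 0.2, 0.9]]).T,
                     samples=["a1", "a2", "b1", "b2"])
        labels = pd.Series(["A", "A", "B", "B"], index=expr.sample_ids)
        model = fc.train_centroids(expr, labels)
        np.testing.assert_allclose(model.centroids["A"], v)

    def test_two_sample_mean(self):
        expr = _expr([[0.0, 2.0, 5.0, 5.0], [2.0, 0.0, 1.0, 1.0]],
                     samples=["a1", "a2", "b1", "b2"])
        labels = pd.Series(["A", "A", "B", "B"], index=expr.sample_ids)
        model = fc.train_centroids(expr, labels)
        np.testing.assert_allclose(model.centroids["A"], [1.0, 1.0])

    def test_matches_column_mean_oracle(self, rng):
        vals = rng.normal(size=(7, 9))
        labels = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                           index=[f"s{j}" for j in range(9)])
        model = fc.train_centroids(_expr(vals), labels)
        for k, cls in enumerate(["A", "B", "C"]):
            np.testing.assert_allclose(
                model.centroids[cls], vals[:, 3 * k:3 * k + 3].mean(axis=1), atol=1e-12
            )

    def test_small_class_rejected(self):
        expr = _expr(np.zeros((3, 3)))
        labels = pd.Series(["A", "A", "B"], index=expr.sample_ids)
        with pytest.raises(fc.ValidationError, match="< 2 samples"):
            fc.train_centroids(expr, labels)

    def test_missing_values_rejected(self):
        vals = np.ones((2, 4))
        vals[0, 0] = np.nan
        expr = _expr(vals)
        labels = pd.Series(["A", "A", "B", "B"], index=expr.sample_ids)
        with pytest.raises(fc.ValidationError, match="missing"):
            fc.train_centroids(expr, labels)


def _random_model(rng, n_genes=10, classes=("A", "B", "C")):
    centroids = pd.DataFrame(
        rng.normal(size=(n_genes, len(classes))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=list(classes),
    )
    return fc.CentroidModel(
        gene_panel=list(centroids.index),
        class_labels=list(classes),
        centroids=centroids,
        scaling=None,
    )


class TestClassify:
    def test_sample_equal_to_centroid_wins_with_correlation_one(self, rng):
        model = _random_model(rng)
        sample = model.centroids["B"].rename("x")
        a = fc.classify(sample, model)
        assert a.label == "B"
        assert a.correlation_to_winner == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        model = _random_model(rng)
        sample = np.exp(2.0 * model.centroids["A"]).rename("x")  # strictly increasing map
        a = fc.classify(sample, model)
        assert a.label == "A"
        assert a.correlation_to_winner == pytest.approx(1.0)

    def test_matches_independent_correlation_oracle(self, rng):
        """100 random samples: the winner equals an argmax over
        independently recomputed Spearman correlations."""
        model = _random_model(rng)
        for i in range(100):
            sample = pd.Series(rng.normal(size=10), index=model.gene_panel, name=f"s{i}")
            a = fc.classify(sample, model)
            oracle = {
                c: stats.spearmanr(sample.to_numpy(), model.centroids[c].to_numpy()).statistic
                for c in model.class_labels
            }
            assert a.label == max(oracle, key=oracle.get)

    def test_low_coverage_error_lists_missing_genes(self, rng):
        model = _random_model(rng)
        sample = pd.Series([0.1, 0.2, 0.3], index=["g0", "g1", "g2"], name="x")
        with pytest.raises(fc.ValidationError, match="g9"):
            fc.classify(sample, model)

    def test_tie_broken_by_class_order_with_warning(self):
        centroids = pd.DataFrame(
            {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]}, index=["g0", "g1", "g2"]
        )
        model = fc.CentroidModel(["g0", "g1", "g2"], ["A", "B"], centroids)
        sample = pd.Series([0.0, 1.0, 2.0], index=["g0", "g1", "g2"], name="x")
        with pytest.warns(UserWarning, match="tie"):
            a = fc.classify(sample, model)
        assert a.label == "A"

    def test_model_roundtrip_through_directory(self, rng, tmp_path):
        model = _random_model(rng)
        model.to_dir(tmp_path / "m")
        back = fc.CentroidModel.from_dir(tmp_path / "m")
        pd.testing.assert_frame_equal(back.centroids, model.centroids)
        assert back.correlation == "spearman"


class TestCrossCorrelation:
    def test_self_correlation_diagonal_one(self, rng):
        model = _random_model(rng)
        mat, matching = fc.centroid_crosscorrelation(model, model)
        np.testing.assert_allclose(np.diag(mat.to_numpy(dtype=float)), 1.0)
        assert all(i == j for i, j, _ in matching)

    def test_permuted_classes_recovered_by_matching(self, rng):
        model = _random_model(rng)
        permuted = fc.CentroidModel(
            gene_panel=model.gene_panel,
            class_labels=["C", "A", "B"],
            centroids=model.centroids[["C", "A", "B"]],
            scaling=None,
        )
        _, matching = fc.centroid_crosscorrelation(model, permuted)
        assert {(i, j) for i, j, _ in matching} == {("A", "A"), ("B", "B"), ("C", "C")}

    def test_small_shared_panel_rejected(self, rng):
        a = _random_model(rng, n_genes=5)
        b = _random_model(rng, n_genes=5)
        b.gene_panel = [f"h{i}" for i in range(5)]
        b.centroids.index = pd.Index(b.gene_panel)
        with pytest.raises(fc.ValidationError):
            fc.centroid_crosscorrelation(a, b)

    def test_matched_pairs_correlate_higher_than_unmatched_across_cohorts(self):
        """Two cohorts from one generating spec: centroid pairs matched by
        true cluster correlate better than mismatched pairs (20 seeds)."""
        wins = 0
        for seed in range(20):
            models = []
            for offset in (0, 1000):
                spec = fc.CohortSpec(
                    n_samples_per_cluster=(30, 30, 30), n_genes=40,
                    n_informative_genes=21, baseline_log2_mean=7.0,
                    seed=seed + offset,
                )
                expr, truth = fc.simulate_expression(spec)
                scaled, scaling = fc.zscore(fc.log2p1(expr))
                models.append(fc.train_centroids(scaled, truth.true_cluster, scaling=scaling))
            mat = fc.centroid_crosscorrelation(models[0], models[1])[0].to_numpy(dtype=float)
            diag = np.diag(mat)
            off = mat[~np.eye(3, dtype=bool)]
            wins += diag.min() > off.max()
        assert wins >= 18


class TestSklearnEstimator:
    def test_fit_predict_recovers_separable_classes(self, rng):
        n, g = 60, 12
        centro = rng.normal(size=(3, g)) * 3
        y = np.repeat([0, 1, 2], n // 3)
        X = centro[y] + rng.normal(size=(n, g)) * 0.5
        est = fc.CorrelationNearestCentroid().fit(X, y)
        assert (est.predict(X) == y).mean() >= 0.95
        assert est.centroids_.shape == (3, g)

    def test_predictions_match_functional_path(self, rng):
        X = rng.normal(size=(20, 8))
        y = np.repeat(["A", "B"], 10)
        est = fc.CorrelationNearestCentroid().fit(X, y)
        genes = [f"g{i}" for i in range(8)]
        expr = fc.ExpressionMatrix(
            pd.DataFrame(X.T, index=genes, columns=[f"s{j}" for j in range(20)]),
            platform="intensity", transform_state="zscored",
        )
        labels = pd.Series(y, index=expr.sample_ids)
        model = fc.train_centroids(expr, labels)
        table = fc.classify_matrix(expr, model)
        np.testing.assert_array_equal(est.predict(X), table["label"].to_numpy())

    def test_get_params_and_clone(self):
        est = fc.CorrelationNearestCentroid(correlation="pearson")
        assert clone(est).get_params()["correlation"] == "pearson"
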