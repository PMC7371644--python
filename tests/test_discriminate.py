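import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from gliaflow.discriminate import (
    crossval_discriminate,
    downsample_events,
    embedding_maps,
    propensity_scores,
    roc_auc,
    tsne_embed,
)
from gliaflow.stats import mann_whitney_u


class TestROCAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        # pos-neg pairs: (0.35,0.1)+, (0.35,0.4)-, (0.8,0.1)+, (0.8,0.4)+
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_equals_mann_whitney_identity(self, rng):
        """AUC == U / (n1 * n0) exactly, on 100 random instances with ties."""
        for _ in range(100):
            n1, n0 = rng.integers(3, 30, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # ties likely
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            u, _ = mann_whitney_u(scores[labels == 1], scores[labels == 0])
            assert roc_auc(scores, labels) == pytest.approx(u / (n1 * n0),
                                                            abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        a1 = roc_auc(scores, labels)
        a2 = roc_auc(np.exp(scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


def two_class_data(rng, n=400, d=4, delta=1.0):
    X = np.vstack([rng.normal(0, 1, size=(n // 2, d)),
                   rng.normal(delta, 1, size=(n // 2, d))])
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return pd.DataFrame(X, columns=[f"m{i}" for i in range(d)]), y


class TestCrossval:
    def test_informative_features_high_auc(self, rng):
        X, y = two_class_data(rng, delta=1.5)
        res = crossval_discriminate(X, y, "logistic", k=5, runs=3, seed=0)
        assert res.auc_mean > 0.8
        assert res.auc_mean == pytest.approx(np.mean(res.per_run_auc))
        assert set(res.feature_contributions) == set(X.columns)

    def test_label_permutation_null(self, rng):
        # n large enough that the null AUC sampling sd (~0.013) keeps the
        # 0.45-0.55 window at > 3 sigma
        X, y = two_class_data(rng, n=2000, delta=1.5)
        y_perm = rng.permutation(y)
        for clf in ("logistic", "rbf_svm"):
            res = crossval_discriminate(X, y_perm, clf, k=5, runs=1, seed=0)
            assert 0.45 <= res.auc_mean <= 0.55

    def test_duplicated_feature_invariance_logistic(self, rng):
        X, y = two_class_data(rng, delta=1.0)
        X2 = pd.concat([X, X.add_suffix("_copy")], axis=1)
        r1 = crossval_discriminate(X, y, "logistic", k=5, runs=2, seed=3)
        r2 = crossval_discriminate(X2, y, "logistic", k=5, runs=2, seed=3)
        assert r1.auc_mean == pytest.approx(r2.auc_mean, abs=0.01)

    def test_small_class_reduces_k(self, rng):
        X, y = two_class_data(rng, n=20)
        res = crossval_discriminate(X, y, "logistic", k=50, runs=1, seed=0)
        assert 0.0 <= res.auc_mean <= 1.0  # ran despite k > class size

    def test_nonbinary_labels_rejected(self, rng):
        X, _ = two_class_data(rng)
        with pytest.raises(ValueError, match="binary"):
            crossval_discriminate(X, np.arange(len(X)) % 3, "logistic")


class TestPropensity:
    def test_scores_in_unit_interval_and_ordered(self, rng):
        X, y = two_class_data(rng, delta=1.2)
        res = crossval_discriminate(X, y, "logistic", k=5, runs=1, seed=0)
        scores = propensity_scores(res.model, X)
        assert scores.shape == (len(X),)
        assert (scores >= 0).all() and (scores <= 1).all()
        # injury-generated events score stochastically higher
        assert roc_auc(scores, y) > 0.7

    def test_symmetric_midpoint(self):
        X = pd.DataFrame({"m": [-1.0, -1.0, 1.0, 1.0]})
        y = np.array([0, 0, 1, 1])
        res = crossval_discriminate(X, y, "logistic", k=2, runs=1, seed=0)
        mid = propensity_scores(res.model, pd.DataFrame({"m": [0.0]}))
        assert mid[0] == pytest.approx(0.5, abs=1e-6)

    def test_channel_mismatch_rejected(self, rng):
        X, y = two_class_data(rng)
        res = crossval_discriminate(X, y, "logistic", k=5, runs=1, seed=0)
        with pytest.raises(ValueError, match="channels"):
            propensity_scores(res.model, X.iloc[:, :2])


class TestDownsample:
    def test_identity_when_enough(self):
        np.testing.assert_array_equal(downsample_events(5, 10, seed=0),
                                      np.arange(5))

    def test_deterministic(self):
        i1 = downsample_events(1000, 100, seed=9)
        i2 = downsample_events(1000, 100, seed=9)
        np.testing.assert_array_equal(i1, i2)
        assert len(np.unique(i1)) == 100

    def test_selection_uniform(self):
        counts = np.zeros(10)
        for rep in range(1000):
            counts[downsample_events(10, 5, seed=rep)] += 1
        expected, sd = 500, np.sqrt(1000 * 0.5 * 0.5)
        # 3.9-sigma bound keeps the family-wise false-alarm rate over the
        # 10 simultaneous per-item checks below ~0.1%
        assert (np.abs(counts - expected) < 3.9 * sd).all()


class TestTSNE:
    def test_separated_populations_recovered(self, rng):
        n = 600
        X = np.vstack([rng.normal(0, 1, size=(n // 2, 5)),
                       rng.normal(6, 1, size=(n // 2, 5))])
        truth = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        emb = tsne_embed(X, perplexity=30, n_iter=500, seed=4)
        km = KMeans(2, n_init=10, random_state=0).fit_predict(emb.coordinates)
        agreement = max((km == truth).mean(), (km != truth).mean())
        assert agreement >= 0.95

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.normal(size=(200, 4))
        e1 = tsne_embed(X, perplexity=20, n_iter=300, seed=7)
        e2 = tsne_embed(X, perplexity=20, n_iter=300, seed=7)
        np.testing.assert_array_equal(e1.coordinates, e2.coordinates)

    def test_scatter_channels_dropped(self, rng):
        df = pd.DataFrame(rng.normal(size=(150, 3)),
                          columns=["FSC-A", "CD45", "CD32"])
        emb = tsne_embed(df, perplexity=10, n_iter=300, seed=0)
        assert emb.channels == ["CD45", "CD32"]

    def test_infeasible_perplexity(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(rng.normal(size=(50, 3)), perplexity=30)


class TestEmbeddingMaps:
    def test_constant_channel(self, rng):
        coords = rng.normal(size=(500, 2))
        density, mean_map, _, _ = embedding_maps(coords, np.full(500, 3.0), bins=10)
        assert density.sum() == 500
        assert np.allclose(mean_map.compressed(), 3.0)

    def test_empty_bins_masked(self, rng):
        coords = np.array([[0.0, 0.0], [10.0, 10.0]])
        _, mean_map, _, _ = embedding_maps(coords, np.array([1.0, 2.0]), bins=5)
        assert mean_map.mask.sum() == 23  # only two occupied bins

    def test_misaligned_rejected(self, rng):
        with pytest.raises(ValueError, match="misaligned"):
            embedding_maps(rng.normal(size=(10, 2)), np.zeros(5))

    def test_high_marker_population_localized(self, rng):
        coords = np.vstack([rng.normal(0, 0.5, size=(300, 2)),
                            rng.normal(5, 0.5, size=(300, 2))])
        values = np.r_[np.zeros(300), np.ones(300) * 10]
        _, mean_map, xe, ye = embedding_maps(coords, values, bins=6)
        # bins near the high-marker island average higher than the others
        assert mean_map.max() > 9.5 and mean_map.min() < 0.5
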