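"""Factor analysis and the layered KNN, against brute-force oracles."""

import numpy as np
import pytest

from eegens.fa_lknn import (
    FALKNNPipeline,
    fa_transform,
    fit_fa_lknn,
    fit_factor_model,
    lknn_fit,
    lknn_predict,
    tukey_quartiles,
)
from eegens.featurebank import FeatureTable


def _table(values, labels):
    values = np.asarray(values, dtype=float)
    return FeatureTable(
        values=values,
        feature_names=[f"f{i}" for i in range(values.shape[1])],
        labels=np.asarray(labels, dtype=int),
    )


def brute_force_lknn(points, labels, weights, queries, k):
    """Literal re-implementation of the layered voting rule: k nearest
    (ties to lower index), inverse-distance association, layer-weighted
    class sums, normalized scores, argmax with ties to the lower class."""
    classes = sorted(set(int(c) for c in labels))
    out_labels, out_scores = [], []
    for q in queries:
        d = np.array([np.linalg.norm(p - q) for p in points])
        order = sorted(range(len(points)), key=lambda j: (d[j], j))[:k]
        if any(d[j] == 0 for j in order):
            j0 = next(j for j in order if d[j] == 0)
            out_labels.append(int(labels[j0]))
            out_scores.append(
                {c: float(c == labels[j0]) for c in classes}
            )
            continue
        ad = {c: 0.0 for c in classes}
        for j in order:
            ad[int(labels[j])] += weights[j] / d[j]
        total = sum(ad.values())
        scores = {c: ad[c] / total for c in classes}
        best = max(classes, key=lambda c: (scores[c], -c))
        out_labels.append(int(best))
        out_scores.append(scores)
    return np.array(out_labels), out_scores


class TestQuartiles:
    def test_tukey_hinges_on_one_to_twelve(self):
        q1, q2, q3 = tukey_quartiles(range(1, 13))
        assert (q1, q2, q3) == (3.5, 6.5, 9.5)

    def test_odd_count_includes_median_in_both_halves(self):
        q1, q2, q3 = tukey_quartiles([1, 2, 3, 4, 5])
        assert (q1, q2, q3) == (2.0, 3.0, 4.0)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            tukey_quartiles([1, 2, 3])


class TestFactorModel:
    def test_generative_recovery(self):
        """Two-factor data, n = 5000: implied covariance matches the
        sample covariance within 5% relative Frobenius error."""
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, (10, 2))
        psi = rng.uniform(0.2, 0.5, 10)
        x = rng.normal(0, 1, (5000, 2)) @ w.T + rng.normal(
            0, np.sqrt(psi), (5000, 10)
        )
        model = fit_factor_model(_table(x, np.zeros(5000)), 2)
        c = np.cov(x.T)
        rel = np.linalg.norm(c - model.implied_covariance()) / np.linalg.norm(c)
        assert rel <= 0.05

    def test_pure_noise_yields_small_loadings(self):
        """With no factor structure the ML loadings absorb only the
        Marchenko-Pastur excess of the top sample eigenvalue
        (~ sqrt(2 psi sqrt(q/n)) ~ 0.17 here)."""
        rng = np.random.default_rng(1)
        psi = rng.uniform(0.2, 0.5, 10)
        x = rng.normal(0, np.sqrt(psi), (5000, 10))
        model = fit_factor_model(_table(x, np.zeros(5000)), 2)
        assert np.linalg.norm(model.loadings, axis=0).max() <= 0.25

    def test_transform_is_the_posterior_linear_map(self):
        """Scores equal the fitted linear projection of centered data."""
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (200, 6))
        tab = _table(x, np.zeros(200))
        model = fit_factor_model(tab, 2)
        scores = fa_transform(model, tab)
        again = fa_transform(model, tab)
        assert np.array_equal(scores.values, again.values)
        assert scores.values.shape == (200, 2)
        # linearity: transform of a row difference = difference of transforms
        delta = model._sk.transform(x[:1]) - model._sk.transform(x[1:2])
        direct = model._sk.transform(x[:1] - x[1:2] + model.mean)
        assert np.allclose(delta, direct, atol=1e-8)

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (100, 4))
        x[:, 2] = 7.0
        model = fit_factor_model(_table(x, np.zeros(100)), 2)
        assert "f2" not in model.feature_names

    def test_invalid_factor_count(self):
        rng = np.random.default_rng(4)
        tab = _table(rng.normal(0, 1, (50, 3)), np.zeros(50))
        with pytest.raises(ValueError):
            fit_factor_model(tab, 0)
        with pytest.raises(ValueError):
            fit_factor_model(tab, 3)


class TestLKNNFit:
    def test_fences_allow_uniform_distances(self):
        """Distances 1..12: V_high = 9.5 + 1.5*6 = 18.5, so nothing is
        rejected."""
        rng = np.random.default_rng(0)
        # place class members at controlled distances from the origin
        dirs = rng.normal(0, 1, (12, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = dirs * np.arange(1, 13)[:, None]
        pts = pts - pts.mean(axis=0)  # center is the mean, distances differ
        other = rng.normal(10, 0.5, (8, 3))
        tab = _table(
            np.vstack([pts, other]), np.r_[np.zeros(12, int), np.ones(8, int)]
        )
        cmap = lknn_fit(tab, 4)
        assert len(cmap.points) == 20

    def test_f_max_and_layer_width(self):
        cls0 = np.array([[0.0, 0], [10, 0], [0, 10], [-10, 0], [0, -10]])
        cls1 = np.array([[100.0, 0], [106, 0], [100, 6], [94, 0], [100, -6]])
        tab = _table(np.vstack([cls0, cls1]), [0] * 5 + [1] * 5)
        cmap = lknn_fit(tab, 5)
        assert cmap.f_max == pytest.approx(10.0, rel=1e-6)
        assert cmap.layer_width == pytest.approx(2.0, rel=1e-6)

    def test_planted_outlier_rejected(self):
        """A member at ten class radii lands beyond the upper fence in
        every seeded trial."""
        rejected = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = rng.normal(0, 1, (30, 3))
            base[0] = 30.0
            other = rng.normal(15, 1, (30, 3))
            tab = _table(
                np.vstack([base, other]),
                np.r_[np.zeros(30, int), np.ones(30, int)],
            )
            cmap = lknn_fit(tab, 4)
            outlier_kept = any(
                np.allclose(p, base[0]) for p in cmap.points
            )
            rejected += not outlier_kept
        assert rejected == 50

    def test_rejection_is_idempotent(self):
        """Refitting on the retained members rejects (almost) nothing new."""
        clean = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.vstack(
                [rng.normal(0, 1, (25, 4)), rng.normal(4, 1, (25, 4))]
            )
            y = np.r_[np.zeros(25, int), np.ones(25, int)]
            cmap = lknn_fit(_table(x, y), 4)
            refit = lknn_fit(_table(cmap.points, cmap.labels), 4)
            clean += len(refit.points) == len(cmap.points)
        assert clean >= 95

    def test_small_class_rejected(self):
        tab = _table(np.random.default_rng(0).normal(0, 1, (7, 2)),
                     [0, 0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="class 1"):
            lknn_fit(tab, 4)


class TestLKNNPredict:
    def test_hand_worked_two_neighbor_case(self, ):
        """Query equidistant (d=1) from a weight-2 class-0 member and a
        weight-1 class-1 member: affiliations (2, 1), scores (2/3, 1/3),
        target class 0."""
        from eegens.fa_lknn import LayeredClassMap

        cmap = LayeredClassMap(
            classes=[], points=np.array([[0.0, 0.0], [2.0, 0.0]]),
            labels=np.array([0, 1]), layer_index=np.array([1, 2]),
            layer_weight=np.array([2.0, 1.0]), f_max=4.0, n_layers=2,
        )
        labels, decisions = lknn_predict(cmap, np.array([[1.0, 0.0]]), k=2)
        assert labels[0] == 0
        assert decisions[0].affiliation == {0: 2.0, 1: 1.0}
        assert decisions[0].scores[0] == pytest.approx(2 / 3)
        assert decisions[0].scores[1] == pytest.approx(1 / 3)

    def test_coincident_query_takes_member_class(self):
        from eegens.fa_lknn import LayeredClassMap

        cmap = LayeredClassMap(
            classes=[], points=np.array([[0.0, 0.0], [2.0, 0.0]]),
            labels=np.array([0, 1]), layer_index=np.array([1, 1]),
            layer_weight=np.array([1.0, 1.0]), f_max=2.0, n_layers=1,
        )
        labels, _ = lknn_predict(cmap, np.array([[2.0, 0.0]]), k=2)
        assert labels[0] == 1

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        """Random small instances: identical labels and scores within
        1e-9 of the literal rule (10 instances per trial = 200 total)."""
        rng = np.random.default_rng(trial)
        n, dim = int(rng.integers(10, 31)), int(rng.integers(1, 5))
        x = np.vstack(
            [rng.normal(0, 1, (n // 2, dim)), rng.normal(2, 1, (n - n // 2, dim))]
        )
        y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
        if min(n // 2, n - n // 2) < 4:
            return
        L = int(rng.integers(1, 5))
        k = int(rng.integers(1, 6))
        cmap = lknn_fit(_table(x, y), L)
        queries = rng.normal(1, 1.5, (10, dim))
        ours, decisions = lknn_predict(cmap, queries, k=k)
        expect, scores = brute_force_lknn(
            cmap.points, cmap.labels, cmap.layer_weight, queries, k
        )
        assert np.array_equal(ours, expect)
        for dec, ref in zip(decisions, scores):
            for c in ref:
                assert dec.scores[c] == pytest.approx(ref[c], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_layer_reduces_to_inverse_distance_knn(self, seed):
        """With L = 1 every weight is 1, so the rule must equal plain
        inverse-distance-weighted KNN."""
        rng = np.random.default_rng(seed)
        x = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(2.5, 1, (20, 3))])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        cmap = lknn_fit(_table(x, y), 1)
        queries = rng.normal(1.2, 1.5, (25, 3))
        ours, _ = lknn_predict(cmap, queries, k=5)
        # inverse-distance-weighted vote over the same retained points
        ref = []
        for q in queries:
            d = np.linalg.norm(cmap.points - q, axis=1)
            order = sorted(range(len(d)), key=lambda j: (d[j], j))[:5]
            if any(d[j] == 0 for j in order):
                ref.append(int(cmap.labels[next(j for j in order if d[j] == 0)]))
                continue
            w = {0: 0.0, 1: 0.0}
            for j in order:
                w[int(cmap.labels[j])] += 1.0 / d[j]
            ref.append(0 if w[0] >= w[1] else 1)
        assert np.array_equal(ours, np.array(ref))

    def test_scores_sum_to_one(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(3, 1, (15, 2))])
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        cmap = lknn_fit(_table(x, y), 3)
        _, decisions = lknn_predict(cmap, rng.normal(1.5, 2, (500, 2)), k=4)
        for dec in decisions:
            assert sum(dec.scores.values()) == pytest.approx(1.0, abs=1e-12)

    def test_k_bounds(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(3, 1, (10, 2))])
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        cmap = lknn_fit(_table(x, y), 2)
        with pytest.raises(ValueError):
            lknn_predict(cmap, x[:1], k=0)
        with pytest.raises(ValueError):
            lknn_predict(cmap, x[:1], k=100)


class TestPipeline:
    def test_easy_benchmark_and_determinism(self, small_features, small_split):
        tr = small_features.subset_rows(small_split.train_indices)
        te = small_features.subset_rows(small_split.test_indices)
        pipe = fit_fa_lknn(tr, n_factors=8, n_layers=4, k=5)
        acc = (pipe.predict(te) == te.labels).mean()
        assert acc >= 0.90
        pipe2 = fit_fa_lknn(tr, n_factors=8, n_layers=4, k=5)
        assert pipe.manifest() == pipe2.manifest()
        assert np.array_equal(pipe.predict(te), pipe2.predict(te))
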